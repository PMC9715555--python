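"""Core session container and shared conventions.

All time bins are half-open ``[t, t + dt)`` with 0-based indices. Paw
velocities are sampled on a 10 ms grid (mm per 10 ms), behavior labels on a
500 ms grid, and population analyses use 100 ms bins; all three grids share
the session clock starting at t = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

#: Canonical behavior classes, in the fixed order used for rank tie-breaking.
CLASSES: tuple[str, ...] = ("step", "turn", "drink", "groom", "rear", "rest")
UNLABELED = "unlabeled"

#: Paw order of the velocity-trace columns.
PAWS: tuple[str, ...] = ("front_left", "front_right", "hind_left", "hind_right")

AREAS: tuple[str, ...] = ("M2", "M1", "S1")
HEMISPHERES: tuple[str, ...] = ("L", "R")
REGIONS: tuple[str, ...] = ("forelimb", "hindlimb")

VEL_BIN_S = 0.01      # paw velocity / spike binning resolution
SNIPPET_S = 0.5       # behavior label resolution
POP_BIN_S = 0.1       # population (embedding) bin size
SWING_THRESHOLD = 0.3  # mm per 10 ms

#: Required columns of the unit metadata table.
UNIT_COLUMNS = ("unit_id", "area", "hemisphere", "region", "snr", "single_unit")


def contralateral_paw(hemisphere: str, region: str) -> str:
    """Paw controlled contralaterally by a unit's hemisphere and limb region."""
    side = "right" if hemisphere == "L" else "left"
    limb = "front" if region == "forelimb" else "hind"
    return f"{limb}_{side}"


def ipsilateral_paw(hemisphere: str, region: str) -> str:
    side = "left" if hemisphere == "L" else "right"
    limb = "front" if region == "forelimb" else "hind"
    return f"{limb}_{side}"


@dataclass
class Session:
    """One recording (or simulated) session.

    Parameters
    ----------
    spike_times
        Per unit, sorted spike times in seconds within ``[0, duration_s]``.
    units
        Metadata table with columns :data:`UNIT_COLUMNS`.
    paw_velocity
        ``(n_10ms_bins, 4)`` horizontal speeds in mm per 10 ms, columns in
        :data:`PAWS` order.
    labels
        ``(n_500ms_snippets,)`` behavior class per snippet (may contain
        ``"unlabeled"``).
    duration_s
        Session duration in seconds.
    meta
        Free-form provenance (subject id, seeds, generator config, ...).
    """

    spike_times: list[np.ndarray]
    units: pd.DataFrame
    paw_velocity: np.ndarray
    labels: np.ndarray
    duration_s: float
    meta: dict = field(default_factory=dict)

    @property
    def n_units(self) -> int:
        return len(self.spike_times)

    def validate(self) -> None:
        """Check internal consistency; raise ``ValueError`` naming the defect."""
        if self.n_units != len(self.units):
            raise ValueError(
                f"units table has {len(self.units)} rows for "
                f"{self.n_units} spike trains"
            )
        missing = [c for c in UNIT_COLUMNS if c not in self.units.columns]
        if missing:
            raise ValueError(f"units table missing columns: {missing}")
        for i, st in enumerate(self.spike_times):
            if len(st) and (st.min() < 0 or st.max() > self.duration_s):
                bad = int(np.argmax((st < 0) | (st > self.duration_s)))
                raise ValueError(
                    f"unit {i}: spike time {st[bad]:.4f} s outside "
                    f"[0, {self.duration_s}] at row {bad}"
                )
        n10 = int(round(self.duration_s / VEL_BIN_S))
        if self.paw_velocity.shape != (n10, 4):
            raise ValueError(
                f"paw_velocity shape {self.paw_velocity.shape} != ({n10}, 4)"
            )
        n500 = int(round(self.duration_s / SNIPPET_S))
        if len(self.labels) != n500:
            raise ValueError(f"label track length {len(self.labels)} != {n500}")
        valid = set(CLASSES) | {UNLABELED}
        bad_labels = set(np.unique(self.labels)) - valid
        if bad_labels:
            raise ValueError(f"unknown behavior labels: {sorted(bad_labels)}")

    def spike_counts(self, bin_s: float = VEL_BIN_S) -> np.ndarray:
        """Bin all spike trains; returns ``(n_units, n_bins)`` int counts."""
        n_bins = int(round(self.duration_s / bin_s))
        edges = np.arange(n_bins + 1) * bin_s
        out = np.zeros((self.n_units, n_bins), dtype=np.int32)
        for i, st in enumerate(self.spike_times):
            out[i], _ = np.histogram(st, bins=edges)
        return out

    def firing_rates(self) -> np.ndarray:
        return np.array([len(st) for st in self.spike_times]) / self.duration_s


def make_units_table(records: Sequence[dict]) -> pd.DataFrame:
    """Build a unit metadata table, filling optional fields with defaults."""
    df = pd.DataFrame(records)
    if "unit_id" not in df:
        df["unit_id"] = np.arange(len(df))
    if "snr" not in df:
        df["snr"] = np.nan
    if "single_unit" not in df:
        df["single_unit"] = True
    if "region" not in df:
        df["region"] = "unknown"
    return df[list(UNIT_COLUMNS)]
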