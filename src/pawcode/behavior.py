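"""Swing-stance binarization of paw velocities and label-track handling.

Paw movement is reduced to a binary swing (moving) / stance (not moving)
series by thresholding horizontal speed at 0.3 mm per 10 ms; a sample is
swing iff its speed strictly exceeds the threshold, so boundary values count
as stance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .session import SNIPPET_S, SWING_THRESHOLD, UNLABELED, VEL_BIN_S

#: Number of 10 ms bins per 500 ms label snippet.
BINS_PER_SNIPPET = int(round(SNIPPET_S / VEL_BIN_S))


@dataclass
class SwingStanceSeries:
    """Binary paw-status series at 10 ms resolution (1 = swing, 0 = stance)."""

    values: np.ndarray
    paw: str
    threshold: float = SWING_THRESHOLD


@dataclass
class LabelTrack:
    """Behavior class per 500 ms snippet, aligned to the 10 ms grid.

    ``offset_s`` is the clock offset of snippet 0 relative to velocity bin 0;
    it is zero for all data produced by this package.
    """

    labels: np.ndarray
    offset_s: float = 0.0


def binarize_paw(
    velocity: np.ndarray, threshold: float = SWING_THRESHOLD, paw: str = "front_left"
) -> SwingStanceSeries:
    """Threshold a horizontal-speed trace into a swing-stance series.

    Parameters
    ----------
    velocity
        Speeds in mm per 10 ms; must be finite.
    threshold
        Swing threshold in the same unit (default 0.3); strictly exceeded
        values are swing.
    """
    velocity = np.asarray(velocity, dtype=float)
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    bad = ~np.isfinite(velocity)
    if bad.any():
        raise ValueError(f"non-finite velocity at index {int(np.argmax(bad))}")
    return SwingStanceSeries((velocity > threshold).astype(np.uint8), paw, threshold)


def step_statistics(series: SwingStanceSeries) -> tuple[float, float]:
    """Steps per second (stance-to-swing transitions) and stance fraction."""
    v = np.asarray(series.values)
    if v.size == 0:
        raise ValueError("empty swing-stance series")
    steps = int(np.sum((v[1:] == 1) & (v[:-1] == 0)))
    duration = v.size * VEL_BIN_S
    return steps / duration, float(np.mean(1 - v))


def expand_labels(track: LabelTrack) -> np.ndarray:
    """Repeat each 500 ms snippet label over its fifty 10 ms bins."""
    if track.offset_s != 0.0:
        raise ValueError("misaligned clocks: non-zero label-track offset")
    return np.repeat(np.asarray(track.labels), BINS_PER_SNIPPET)


def contract_labels(per_bin: np.ndarray) -> LabelTrack:
    """Inverse of :func:`expand_labels` by per-snippet majority vote."""
    per_bin = np.asarray(per_bin)
    if per_bin.size % BINS_PER_SNIPPET:
        raise ValueError(
            f"length {per_bin.size} is not a multiple of {BINS_PER_SNIPPET}"
        )
    snippets = per_bin.reshape(-1, BINS_PER_SNIPPET)
    out = []
    for row in snippets:
        vals, counts = np.unique(row, return_counts=True)
        out.append(vals[np.argmax(counts)])
    return LabelTrack(np.array(out, dtype=per_bin.dtype))


def labels_on_pop_grid(track: LabelTrack, pop_bin_s: float = 0.1) -> np.ndarray:
    """Label per 100 ms population bin; a bin inherits its snippet's label."""
    per_snippet = int(round(SNIPPET_S / pop_bin_s))
    return np.repeat(np.asarray(track.labels), per_snippet)


def is_labeled(labels: np.ndarray) -> np.ndarray:
    return np.asarray(labels) != UNLABELED
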