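"""Spike-triggered average paw swing-stance status (STAPSSS) statistics.

For each unit and paw, the STAPSSS is the average of the paw's binary
swing-stance series in +-1 s windows (201 bins of 10 ms) around every spike,
normalized by the waveform mean. Coupling is the ratio ``c`` of the
waveform's standard deviation to the 0.99-quantile standard deviation of a
shift-bootstrap null (1000 circularly rotated spike trains); ``c > 1`` marks
a significantly coupled unit. Circular rotation preserves the marginals and
the autocorrelation of both series, so autocorrelated paw movement alone
cannot produce false positives.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .behavior import SwingStanceSeries
from .session import CLASSES, VEL_BIN_S

WINDOW_BINS = 100          # +-1 s at 10 ms
WAVEFORM_LEN = 2 * WINDOW_BINS + 1
MIN_RATE_HZ = 0.1
N_SHIFTS = 1000
CONTROL_QUANTILE = 0.99


@dataclass
class StapsssResult:
    """STAPSSS waveform and coupling statistics for one unit and paw."""

    waveform: np.ndarray           # length 201, mean-normalized
    waveform_std: float
    control_q99_std: float | None = None
    coupling: float | None = None
    significant: bool | None = None
    peak_offset_ms: float | None = None


def _check_inputs(spike_bins: np.ndarray, status: np.ndarray) -> None:
    if len(spike_bins) != len(status):
        raise ValueError(
            f"spike bins ({len(spike_bins)}) and status ({len(status)}) "
            "must share length"
        )


def compute_stapsss(
    spike_bins: np.ndarray, status: SwingStanceSeries | np.ndarray
) -> StapsssResult:
    """Average the swing-stance status in +-1 s windows around every spike.

    Bins holding ``k`` spikes contribute ``k`` times. Windows clipped at the
    recording edges are excluded (zero-padding would bias the waveform mean).
    The waveform is divided by its mean, so its standard deviation is
    invariant to uniform rescaling of the status series.
    """
    values = status.values if isinstance(status, SwingStanceSeries) else status
    spike_bins = np.asarray(spike_bins)
    values = np.asarray(values, dtype=float)
    _check_inputs(spike_bins, values)
    rate = spike_bins.sum() / (len(spike_bins) * VEL_BIN_S)
    if rate < MIN_RATE_HZ:
        raise ValueError(
            f"unit firing rate {rate:.4f} Hz below the {MIN_RATE_HZ} Hz minimum"
        )
    centers = np.nonzero(spike_bins)[0]
    inside = (centers >= WINDOW_BINS) & (centers < len(values) - WINDOW_BINS)
    centers = centers[inside]
    if centers.size == 0:
        raise ValueError("zero usable spikes after edge-window exclusion")
    weights = spike_bins[centers].astype(float)
    offsets = np.arange(-WINDOW_BINS, WINDOW_BINS + 1)
    windows = values[centers[:, None] + offsets]
    raw = weights @ windows / weights.sum()
    mean = raw.mean()
    waveform = raw / mean if mean > 0 else raw
    return StapsssResult(waveform=waveform, waveform_std=float(waveform.std()))


def _circular_moving_moments(r: np.ndarray, win: int) -> tuple[np.ndarray, np.ndarray]:
    """Circular moving sum of ``r`` and ``r**2`` over centered ``win`` windows."""
    half = win // 2
    padded = np.concatenate([r[-half:], r, r[:half]])
    c1 = np.concatenate([[0.0], np.cumsum(padded)])
    c2 = np.concatenate([[0.0], np.cumsum(padded**2)])
    s1 = c1[win:] - c1[:-win]
    s2 = c2[win:] - c2[:-win]
    return s1, s2


def shift_null(
    spike_bins: np.ndarray,
    status: SwingStanceSeries | np.ndarray,
    n_shifts: int = N_SHIFTS,
    seed: int | None = 0,
) -> float:
    """0.99-quantile waveform std over circularly shifted spike trains.

    Each shift rotates the spike train by a uniform random offset at least
    1 s away from the zero shift and recomputes the mean-normalized STAPSSS
    standard deviation. After rotation the series is treated as circular, so
    every spike keeps a full +-1 s window. All shifts are evaluated at once
    through one FFT cross-correlation plus sliding-window moments. The
    quantile uses numpy's inclusive (type-7) convention.
    """
    if n_shifts < 100:
        raise ValueError("n_shifts must be >= 100")
    values = status.values if isinstance(status, SwingStanceSeries) else status
    spike_bins = np.asarray(spike_bins, dtype=float)
    values = np.asarray(values, dtype=float)
    _check_inputs(spike_bins, values)
    T = len(values)
    if T * VEL_BIN_S < 4.0:
        raise ValueError("recording shorter than 4 s")
    n_spikes = spike_bins.sum()
    if n_spikes == 0:
        raise ValueError("zero spikes")

    # r[tau] = sum_t spikes[t] * status[(t + tau) mod T]
    r = np.fft.irfft(
        np.conj(np.fft.rfft(spike_bins)) * np.fft.rfft(values), n=T
    )
    s1, s2 = _circular_moving_moments(r, WAVEFORM_LEN)
    mean = s1 / (WAVEFORM_LEN * n_spikes)
    var = np.maximum(s2 / (WAVEFORM_LEN * n_spikes**2) - mean**2, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        cv = np.where(mean > 0, np.sqrt(var) / mean, 0.0)

    rng = np.random.default_rng(seed)
    offsets = rng.integers(WINDOW_BINS, T - WINDOW_BINS, size=n_shifts)
    return float(np.quantile(cv[offsets], CONTROL_QUANTILE))


def stapsss_coupling(
    spike_bins: np.ndarray,
    status: SwingStanceSeries | np.ndarray,
    n_shifts: int = N_SHIFTS,
    seed: int | None = 0,
) -> StapsssResult:
    """Full STAPSSS analysis of one unit/paw: waveform, null, coupling, offset."""
    res = compute_stapsss(spike_bins, status)
    q99 = shift_null(spike_bins, status, n_shifts=n_shifts, seed=seed)
    if q99 > 0:
        c = res.waveform_std / q99
    else:
        c = np.inf if res.waveform_std > 0 else 0.0
    res.control_q99_std = q99
    res.coupling = float(c)
    res.significant = bool(c > 1)
    res.peak_offset_ms = peak_offset(res.waveform) if res.significant else None
    return res


def peak_offset(waveform: np.ndarray) -> float | None:
    """Signed offset (ms) of the largest waveform deviation from 1.

    Negative offsets mean the movement peak precedes the spike. Ties are
    broken toward 0, then toward the earlier bin.
    """
    dev = np.abs(np.asarray(waveform) - 1.0)
    peak = dev.max()
    if peak <= 1e-12:
        return None
    candidates = np.nonzero(np.isclose(dev, peak, rtol=0, atol=1e-12))[0]
    idx = min(candidates, key=lambda i: (abs(int(i) - WINDOW_BINS), int(i)))
    return float(10 * (int(idx) - WINDOW_BINS))


def coupling_and_bias(
    coupling_table: pd.DataFrame, units: pd.DataFrame
) -> pd.DataFrame:
    """Contralateral bias per unit and paw pair.

    ``coupling_table`` holds columns (unit_id, paw, coupling). Bias is
    ``b = c_r / c_l`` for left-hemisphere units and ``b = c_l / c_r`` for
    right-hemisphere units (equivalently contralateral over ipsilateral),
    computed separately for the front and hind pairs. A zero ipsilateral
    coupling leaves the bias undefined (NaN).
    """
    wide = coupling_table.pivot(index="unit_id", columns="paw", values="coupling")
    rows = []
    for _, unit in units.iterrows():
        hemi = unit["hemisphere"]
        for pair in ("front", "hind"):
            c_l = wide.loc[unit["unit_id"], f"{pair}_left"]
            c_r = wide.loc[unit["unit_id"], f"{pair}_right"]
            num, den = (c_r, c_l) if hemi == "L" else (c_l, c_r)
            b = num / den if den > 0 else np.nan
            rows.append(
                {
                    "unit_id": unit["unit_id"],
                    "pair": pair,
                    "area": unit["area"],
                    "hemisphere": hemi,
                    "bias": b,
                }
            )
    return pd.DataFrame(rows)


def stapsss_table(
    session,
    n_shifts: int = N_SHIFTS,
    seed: int = 0,
    min_rate_hz: float = MIN_RATE_HZ,
) -> pd.DataFrame:
    """Run the STAPSSS analysis for every unit x paw of a session.

    Returns one row per (unit, paw) with coupling, significance and peak
    offset; units below the firing-rate floor are skipped.
    """
    from .behavior import binarize_paw
    from .session import PAWS

    spike_bins = session.spike_counts(VEL_BIN_S)
    statuses = {
        paw: binarize_paw(session.paw_velocity[:, i], paw=paw)
        for i, paw in enumerate(PAWS)
    }
    rows = []
    rates = session.firing_rates()
    for u in range(session.n_units):
        if rates[u] < min_rate_hz:
            continue
        for p_idx, paw in enumerate(PAWS):
            res = stapsss_coupling(
                spike_bins[u], statuses[paw], n_shifts=n_shifts,
                seed=[seed, u, p_idx],
            )
            rows.append(
                {
                    "unit_id": session.units.iloc[u]["unit_id"],
                    "paw": paw,
                    "coupling": res.coupling,
                    "significant": res.significant,
                    "peak_offset_ms": res.peak_offset_ms,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# behavioral selectivity
# ---------------------------------------------------------------------------

def selectivity_test(
    counts_500ms: np.ndarray,
    labels: np.ndarray,
    alpha: float = 0.05,
    min_samples: int = 5,
) -> pd.DataFrame:
    """Per-class one-sided rank-sum selectivity with BH correction.

    Tests, for each behavior class, whether the unit's 500 ms spike counts
    during the class exceed those during the remainder of the session;
    the six p-values are Benjamini-Hochberg corrected per unit.
    """
    counts_500ms = np.asarray(counts_500ms)
    labels = np.asarray(labels)
    pvals, valid = [], []
    for c in CLASSES:
        in_class = counts_500ms[labels == c]
        rest = counts_500ms[(labels != c) & (labels != "unlabeled")]
        if len(in_class) < min_samples or len(rest) < min_samples:
            pvals.append(np.nan)
            valid.append(False)
            continue
        stat = stats.ranksums(in_class, rest, alternative="greater")
        pvals.append(stat.pvalue)
        valid.append(True)
    pvals = np.asarray(pvals)
    p_adj = np.full(len(CLASSES), np.nan)
    selective = np.zeros(len(CLASSES), dtype=bool)
    mask = np.asarray(valid)
    if mask.any():
        rej, adj, _, _ = multipletests(pvals[mask], alpha=alpha, method="fdr_bh")
        p_adj[mask] = adj
        selective[mask] = rej
    return pd.DataFrame(
        {"class": CLASSES, "p": pvals, "p_adj": p_adj, "selective": selective,
         "tested": mask}
    )


@dataclass
class BalancedKWResult:
    """Class-balanced Kruskal-Wallis summary for one unit."""

    mean_significant_pairs: float
    pair_means: dict[tuple[str, str], float]


def balanced_kruskal_wallis(
    counts_500ms: np.ndarray,
    labels: np.ndarray,
    n_resamples: int = 100,
    alpha: float = 0.05,
    seed: int | None = 0,
    min_samples: int = 5,
) -> BalancedKWResult:
    """Average number of significant class-pair differences for one unit.

    Each resample subsamples every class to the smallest class size, runs a
    Kruskal-Wallis test, and - when significant at ``alpha`` - counts the
    pairwise two-sided rank-sum comparisons significant at ``alpha``. The
    mean count over resamples is returned along with per-pair rates (NaN
    when the smallest class has fewer than ``min_samples`` samples).
    """
    counts_500ms = np.asarray(counts_500ms)
    labels = np.asarray(labels)
    groups = [counts_500ms[labels == c] for c in CLASSES]
    sizes = [len(g) for g in groups]
    if min(sizes) == 0:
        raise ValueError("all six classes must be present")
    n_min = min(sizes)
    if n_min < min_samples:
        warnings.warn(
            f"smallest class has {n_min} < {min_samples} samples; skipping",
            stacklevel=2,
        )
        return BalancedKWResult(np.nan, {})
    rng = np.random.default_rng(seed)
    pairs = list(combinations(range(len(CLASSES)), 2))
    pair_hits = {p: 0 for p in pairs}
    totals = []
    for _ in range(n_resamples):
        sub = [rng.choice(g, size=n_min, replace=False) for g in groups]
        try:
            _, p = stats.kruskal(*sub)
        except ValueError:  # all values identical
            p = 1.0
        n_sig = 0
        if p < alpha:
            for a, b in pairs:
                if stats.ranksums(sub[a], sub[b]).pvalue < alpha:
                    n_sig += 1
                    pair_hits[(a, b)] += 1
        totals.append(n_sig)
    pair_means = {
        (CLASSES[a], CLASSES[b]): hits / n_resamples
        for (a, b), hits in pair_hits.items()
    }
    return BalancedKWResult(float(np.mean(totals)), pair_means)
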