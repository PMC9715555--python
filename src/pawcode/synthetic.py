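"""Multi-subject synthetic session generator.

The generator is a synthetic stand-in for the structure the analysis assumes
in real recordings; no generative model of the data exists, so all
distributional choices here are explicit package choices (see
``docs/methods.md``):

* six behavior classes occupy the session as independent geometric-dwell
  segments whose stationary time fractions equal the configured class
  weights;
* each class has a shared latent *archetype*; the population's latent state
  follows the current class's archetype plus a smooth AR(1) fluctuation
  (shared across units), emulating the autocorrelated trial-to-trial
  variability of cortical populations; a unit's rate is an exponential link
  of a bounded linear readout of that latent state through a non-negative
  mixing vector drawn per subject;
* paw-swing-locked rate gains follow an anterior-to-posterior gradient
  (M2 < M1 < S1) and are larger for the contralateral paw, emulating the
  lateralized coupling gradient of sensorimotor cortex;
* spikes are inhomogeneous Poisson counts in 10 ms bins.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .behavior import BINS_PER_SNIPPET, LabelTrack, binarize_paw
from .session import (
    AREAS,
    CLASSES,
    HEMISPHERES,
    PAWS,
    REGIONS,
    SNIPPET_S,
    SWING_THRESHOLD,
    VEL_BIN_S,
    Session,
    contralateral_paw,
    ipsilateral_paw,
    make_units_table,
)

#: Default contralateral swing gains: coupling grows anterior -> posterior.
DEFAULT_SWING_GAINS = {
    (area, hemi): gain
    for area, gain in (("M2", 1.3), ("M1", 1.7), ("S1", 2.2))
    for hemi in HEMISPHERES
}

#: Default stationary class weights (imbalanced, rest- and step-heavy).
DEFAULT_CLASS_WEIGHTS = {
    "step": 0.30, "turn": 0.15, "drink": 0.10,
    "groom": 0.10, "rear": 0.10, "rest": 0.25,
}

#: Default mean dwell times per class, seconds.
DEFAULT_DWELL_S = {
    "step": 2.0, "turn": 1.5, "drink": 2.5,
    "groom": 4.0, "rear": 2.0, "rest": 5.0,
}

#: Per-class log-rate offsets along the all-ones latent direction. Because
#: mixing vectors are non-negative and sum to one, an offset of delta adds
#: delta to every unit's log rate during the class: movement classes recruit
#: the population, rest lowers it. Offsets scale with archetype_separation,
#: so a zero separation still implies no class signal at all.
DEFAULT_CLASS_RATE_OFFSETS = {
    "step": 0.20, "turn": 0.10, "drink": -0.05,
    "groom": -0.05, "rear": 0.15, "rest": -0.50,
}


def default_metadata_plan(per_cell: int = 7) -> dict[tuple[str, str, str], int]:
    """Units per (area, hemisphere, somatotopic region); 12 cells."""
    return {
        (a, h, r): per_cell for a in AREAS for h in HEMISPHERES for r in REGIONS
    }


@dataclass
class ArchetypeModel:
    """Shared latent behavior code sampled by every subject.

    ``class_archetypes`` are latent vectors whose pairwise distances scale
    with ``archetype_separation``; ``archetype_separation = 0`` makes all
    archetypes identical (no class signal).
    """

    latent_dim: int
    class_archetypes: dict[str, np.ndarray]
    archetype_separation: float
    swing_gain_by_region: dict[tuple[str, str], float]
    baseline_rate_range: tuple[float, float]
    seed: int
    max_rate_hz: float = 50.0
    predictor_clip: float = 2.5
    ipsi_gain_fraction: float = 0.15
    swing_latency_s_by_area: dict[str, float] = field(default_factory=dict)
    latent_noise_sd: float = 1.0   # sd of the shared AR(1) latent fluctuation
    latent_tau_s: float = 0.5      # its correlation timescale

    def __post_init__(self) -> None:
        if self.latent_dim < 1:
            raise ValueError("latent_dim must be >= 1")
        if self.archetype_separation < 0:
            raise ValueError("archetype_separation must be >= 0")
        for key, g in self.swing_gain_by_region.items():
            if not np.isfinite(g) or g < 0:
                raise ValueError(f"swing gain for {key} must be finite and >= 0")

    @classmethod
    def create(
        cls,
        latent_dim: int = 8,
        archetype_separation: float = 2.0,
        swing_gain_by_region: dict | None = None,
        baseline_rate_range: tuple[float, float] = (2.0, 10.0),
        seed: int = 0,
        class_rate_offsets: dict[str, float] | None = None,
        exchangeable_classes: bool = False,
        **kwargs,
    ) -> "ArchetypeModel":
        """Draw class archetypes from the seed and assemble the model.

        ``exchangeable_classes`` constrains the archetype deviations to be
        mean-free, orthogonal to the all-ones (population-rate) direction
        and of equal norm, while keeping their random pairwise angles.
        Every class then has identical across-unit rate moments; the only
        class signal is the *correlation pattern* of unit rates (fine
        structure), with no coarse rate or dispersion differences. Used
        with zero ``class_rate_offsets`` for fine-structure-only studies.
        """
        rng = np.random.default_rng([seed, 101])
        z = rng.standard_normal((len(CLASSES), latent_dim)) / np.sqrt(latent_dim)
        offsets = dict(DEFAULT_CLASS_RATE_OFFSETS)
        offsets.update(class_rate_offsets or {})
        if exchangeable_classes:
            ones = np.ones(latent_dim) / np.sqrt(latent_dim)
            target = np.mean(np.linalg.norm(z, axis=1))
            for _ in range(4):
                z = z - z.mean(axis=0)
                z = z - np.outer(z @ ones, ones)
                z = z / np.linalg.norm(z, axis=1, keepdims=True) * target
        archetypes = {
            c: archetype_separation * (z[i] + offsets.get(c, 0.0))
            for i, c in enumerate(CLASSES)
        }
        return cls(
            latent_dim=latent_dim,
            class_archetypes=archetypes,
            archetype_separation=archetype_separation,
            swing_gain_by_region=dict(swing_gain_by_region or DEFAULT_SWING_GAINS),
            baseline_rate_range=baseline_rate_range,
            seed=seed,
            **kwargs,
        )


@dataclass
class SessionConfig:
    """Size, composition and behavior statistics of one simulated session."""

    n_units: int = 84
    duration_s: float = 2160.0  # 36 min, the typical recording length
    units_metadata_plan: dict[tuple[str, str, str], int] = field(
        default_factory=default_metadata_plan
    )
    dwell_time_s: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DWELL_S)
    )
    class_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_WEIGHTS)
    )
    seed: int = 0
    steps_per_s: float = 1.22      # gait rate during locomotion bouts
    gait_duty: float = 0.35        # swing fraction of a gait cycle
    subject: str = "synthetic"

    def __post_init__(self) -> None:
        unknown = set(self.class_weights) - set(CLASSES)
        unknown |= set(self.dwell_time_s) - set(CLASSES)
        if unknown:
            raise ValueError(f"unknown class name(s): {sorted(unknown)}")
        total = sum(self.class_weights.values())
        if not np.isclose(total, 1.0):
            raise ValueError(f"class_weights sum to {total}, expected 1")
        plan_total = sum(self.units_metadata_plan.values())
        if plan_total != self.n_units:
            raise ValueError(
                f"units_metadata_plan totals {plan_total} units, "
                f"n_units is {self.n_units}"
            )


# ---------------------------------------------------------------------------
# behavior track
# ---------------------------------------------------------------------------

#: Gait phase offsets per paw (trot-like diagonal pattern).
_PAW_PHASE = {"front_left": 0.0, "front_right": 0.5, "hind_left": 0.5,
              "hind_right": 0.0}

#: Which paws perform gait swings in each class.
_GAIT_PAWS = {
    "step": PAWS,
    "rear": ("front_left", "front_right"),
    "turn": ("front_left", "front_right"),
}
#: Probability that a snippet of the class expresses gait swings at all.
_GAIT_PROB = {"step": 1.0, "rear": 1.0, "turn": 0.3}


def generate_behavior_track(
    config: SessionConfig,
) -> tuple[LabelTrack, np.ndarray]:
    """Simulate the label track and the four paw-velocity traces.

    Classes are laid down as independent segments with geometric dwell in
    500 ms snippet units; segment-entry probabilities are proportional to
    ``class_weights / dwell`` so the stationary time fraction of each class
    equals its configured weight. Velocities are consistent with labels:
    locomotion classes show alternating supra-threshold swing bouts at the
    configured gait rate, rest stays strictly below the swing threshold.
    """
    if config.duration_s < 60:
        raise ValueError("duration must be >= 60 s")
    rng = np.random.default_rng([config.seed, 11])
    n_snippets = int(round(config.duration_s / SNIPPET_S))
    classes = [c for c in CLASSES if config.class_weights.get(c, 0.0) > 0]
    weights = np.array([config.class_weights[c] for c in classes])
    dwell_snips = np.array(
        [max(config.dwell_time_s[c] / SNIPPET_S, 1.0) for c in classes]
    )
    entry_p = weights / dwell_snips
    entry_p /= entry_p.sum()

    labels = np.empty(n_snippets, dtype=object)
    pos = 0
    while pos < n_snippets:
        ci = rng.choice(len(classes), p=entry_p)
        run = rng.geometric(1.0 / dwell_snips[ci])
        labels[pos : pos + run] = classes[ci]
        pos += run
    labels = labels.astype(str)
    # behavior bouts: a new segment starts at every class change
    segment_id = np.concatenate([[0], np.cumsum(labels[1:] != labels[:-1])])

    n_bins = n_snippets * BINS_PER_SNIPPET
    t = np.arange(n_bins) * VEL_BIN_S
    cycle_s = 1.0 / config.steps_per_s
    phase = (t / cycle_s) % 1.0

    per_bin_class = np.repeat(labels, BINS_PER_SNIPPET)
    velocity = np.empty((n_bins, 4))
    # sub-threshold baseline jitter everywhere (strictly below threshold)
    velocity[:] = rng.uniform(0.0, 0.25 * SWING_THRESHOLD, size=(n_bins, 4))

    gait_active = np.zeros(n_snippets, dtype=bool)
    for c, prob in _GAIT_PROB.items():
        mask = labels == c
        gait_active[mask] = rng.random(mask.sum()) < prob
    gait_active_bins = np.repeat(gait_active, BINS_PER_SNIPPET)

    # per-paw, per-segment phase jitter: within a behavior bout the gait is
    # periodic, but the relative phase between paws re-randomizes across
    # bouts (real inter-paw phase relations drift); this keeps the step
    # rate while decorrelating the paws' swing patterns over the session
    n_segments = int(segment_id.max()) + 1
    jitter = rng.random((n_segments, 4))
    seg_bins = np.repeat(segment_id, BINS_PER_SNIPPET)

    for p_idx, paw in enumerate(PAWS):
        paw_phase = phase + _PAW_PHASE[paw] + jitter[seg_bins, p_idx]
        swing_phase = (paw_phase % 1.0) < config.gait_duty
        allowed = np.zeros(n_bins, dtype=bool)
        for c, paws in _GAIT_PAWS.items():
            if paw in paws:
                allowed |= per_bin_class == c
        swing = swing_phase & allowed & gait_active_bins
        n_swing = int(swing.sum())
        velocity[swing, p_idx] = SWING_THRESHOLD * rng.uniform(
            1.5, 4.0, size=n_swing
        )
    return LabelTrack(labels), velocity


# ---------------------------------------------------------------------------
# population tuning
# ---------------------------------------------------------------------------

def generate_population(
    archetypes: ArchetypeModel, config: SessionConfig
) -> pd.DataFrame:
    """Draw one subject's unit tuning table.

    Each unit gets a non-negative mixing vector over the shared latent space
    (Dirichlet(1), drawn from the session/subject seed), a baseline rate
    uniform in ``baseline_rate_range``, and a swing gain from its (area,
    hemisphere) with mild log-normal unit-to-unit jitter.
    """
    rng = np.random.default_rng([config.seed, archetypes.seed, 22])
    rows = []
    for (area, hemi, region), count in sorted(config.units_metadata_plan.items()):
        for _ in range(count):
            rows.append({"area": area, "hemisphere": hemi, "region": region})
    if len(rows) != config.n_units:
        raise ValueError("metadata plan inconsistent with n_units")

    n = len(rows)
    mixing = rng.dirichlet(np.ones(archetypes.latent_dim), size=n)
    lo, hi = archetypes.baseline_rate_range
    baseline = rng.uniform(lo, hi, size=n)
    snr = np.exp(rng.normal(1.2, 0.4, size=n))
    single = rng.random(n) < 0.8
    table = pd.DataFrame(rows)
    table["unit_id"] = np.arange(n)
    table["baseline_hz"] = baseline
    table["snr"] = snr
    table["single_unit"] = single
    gains = np.array(
        [archetypes.swing_gain_by_region[(r["area"], r["hemisphere"])] for r in rows]
    )
    table["swing_gain"] = gains * np.exp(rng.normal(0.0, 0.15, size=n))
    table["latency_s"] = [
        archetypes.swing_latency_s_by_area.get(r["area"], 0.0) for r in rows
    ]
    table["contra_paw"] = [
        contralateral_paw(r["hemisphere"], r["region"]) for r in rows
    ]
    table["ipsi_paw"] = [
        ipsilateral_paw(r["hemisphere"], r["region"]) for r in rows
    ]
    # per-unit class predictors, centered across classes so that the
    # baseline is the across-class geometric-mean rate
    arch_matrix = np.stack([archetypes.class_archetypes[c] for c in CLASSES])
    pred = mixing @ arch_matrix.T              # (n, 6)
    pred -= pred.mean(axis=1, keepdims=True)
    pred = np.clip(pred, -archetypes.predictor_clip, archetypes.predictor_clip)
    for i, c in enumerate(CLASSES):
        table[f"pred_{c}"] = pred[:, i]
    table["mixing"] = list(mixing)
    return table


# ---------------------------------------------------------------------------
# full session
# ---------------------------------------------------------------------------

def latent_trajectory(
    archetypes: ArchetypeModel,
    class_idx: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Shared latent state per 10 ms bin: class archetype + AR(1) fluctuation.

    The fluctuation has unit stationary variance scaled by
    ``latent_noise_sd`` and correlation timescale ``latent_tau_s``; it is
    shared across the population, providing the temporally continuous
    trial-to-trial variability the manifold analysis assumes.
    """
    arch_matrix = np.stack([archetypes.class_archetypes[c] for c in CLASSES])
    base = arch_matrix[class_idx].astype(float)
    sd = archetypes.latent_noise_sd
    if sd > 0:
        from scipy.signal import lfilter

        rho = np.exp(-VEL_BIN_S / archetypes.latent_tau_s)
        innov_sd = np.sqrt(1.0 - rho**2)
        eps = rng.standard_normal(base.shape) * innov_sd
        eps[0] /= innov_sd  # start at stationary variance
        u = lfilter([1.0], [1.0, -rho], eps, axis=0)
        base = base + sd * u
    return base


def expected_rate_traces(
    archetypes: ArchetypeModel,
    population: pd.DataFrame,
    latent: np.ndarray,
    swing_by_paw: dict[str, np.ndarray],
) -> np.ndarray:
    """Deterministic (n_units, T) 10 ms rate traces given behavior + latent.

    Rates follow ``baseline * exp(clip(mix . latent - center))`` times the
    swing-gain terms; the centering makes the baseline the across-class
    geometric-mean rate. A positive ``latency_s`` delays the swing gain
    relative to the movement, i.e. spikes follow the movement
    (sensory-like lag).
    """
    mixing = np.stack(population["mixing"].to_numpy())        # (n, L)
    arch_matrix = np.stack(
        [archetypes.class_archetypes[c] for c in CLASSES]
    )
    center = (mixing @ arch_matrix.T).mean(axis=1)
    pred = mixing @ latent.T - center[:, None]
    np.clip(pred, -archetypes.predictor_clip, archetypes.predictor_clip,
            out=pred)
    rates = population["baseline_hz"].to_numpy()[:, None] * np.exp(pred)
    for i, (_, row) in enumerate(population.iterrows()):
        lag_bins = int(round(row["latency_s"] / VEL_BIN_S))
        g = row["swing_gain"]
        contra = np.roll(swing_by_paw[row["contra_paw"]], lag_bins)
        ipsi = np.roll(swing_by_paw[row["ipsi_paw"]], lag_bins)
        rates[i] *= (1.0 + (g - 1.0) * contra)
        rates[i] *= (1.0 + (g - 1.0) * archetypes.ipsi_gain_fraction * ipsi)
    return np.minimum(rates, archetypes.max_rate_hz)


def generate_session(
    archetypes: ArchetypeModel,
    config: SessionConfig,
    population: pd.DataFrame | None = None,
) -> Session:
    """Simulate one full session (behavior, velocities, Poisson spikes)."""
    track, velocity = generate_behavior_track(config)
    if population is None:
        population = generate_population(archetypes, config)
    per_bin_class = np.repeat(track.labels, BINS_PER_SNIPPET)
    cls_to_i = {c: i for i, c in enumerate(CLASSES)}
    class_idx = np.array([cls_to_i[c] for c in per_bin_class])
    swing_by_paw = {
        paw: binarize_paw(velocity[:, i], paw=paw).values.astype(float)
        for i, paw in enumerate(PAWS)
    }
    rng = np.random.default_rng([config.seed, archetypes.seed, 33])
    latent = latent_trajectory(archetypes, class_idx, rng)
    rates = expected_rate_traces(archetypes, population, latent, swing_by_paw)
    bad = ~np.isfinite(rates).all(axis=1)
    if bad.any():
        raise ValueError(
            f"non-finite firing rate for unit {int(np.argmax(bad))}"
        )
    spike_times = []
    for i in range(len(population)):
        counts = rng.poisson(rates[i] * VEL_BIN_S)
        idx = np.repeat(np.arange(counts.size), counts)
        times = (idx + rng.random(idx.size)) * VEL_BIN_S
        spike_times.append(np.sort(times))

    units = make_units_table(
        population[
            ["unit_id", "area", "hemisphere", "region", "snr", "single_unit"]
        ].to_dict("records")
    )
    session = Session(
        spike_times=spike_times,
        units=units,
        paw_velocity=velocity,
        labels=track.labels,
        duration_s=config.duration_s,
        meta={
            "subject": config.subject,
            "seed": config.seed,
            "archetype_seed": archetypes.seed,
            "archetype_separation": archetypes.archetype_separation,
            "tuning": population,
            "rates": rates,
        },
    )
    session.validate()
    return session
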