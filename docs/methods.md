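# Methods

This note documents the models, parameters and numerical choices behind
`pawcode`, and what the synthetic study conditions do and do not establish.

## Conventions

All time bins are half-open `[t, t + Δ)` with 0-based indices. Three grids
share one session clock: 10 ms (paw velocity, spike binning for single-unit
analyses), 100 ms (population embedding), 500 ms (behavior labels). Spike
times are stored in seconds; binning always happens downstream. The six
behavior classes, in the canonical order used for every deterministic
tie-break, are step, turn, drink, groom, rear, rest.

## Single-unit coupling (STAPSSS)

A paw's horizontal speed trace (mm per 10 ms) is binarized at a strict
threshold of 0.3 mm / 10 ms — boundary values count as stance. For each
unit × paw, the swing–stance series is averaged in ±1 s windows around
every spike (bins holding k spikes contribute k times; windows clipped at
the recording edges are excluded, because zero-padding would bias the
waveform mean) and divided by the waveform mean. Units below 0.1 Hz are
excluded.

The null distribution rotates the spike train circularly by 1000 uniform
random offsets at least 1 s away from zero and recomputes the normalized
waveform standard deviation; coupling is `c = σ / q₀.₉₉` of that null
(empirical quantile, numpy's inclusive type-7 convention), significant if
`c > 1`. Implementation note: after a circular rotation the series has no
edges, so control waveforms use circular windowing; this lets all 1000
shifts be evaluated with a single FFT cross-correlation plus
sliding-window moments per unit (`O(T log T)` instead of
`O(n_shifts · n_spikes)`), and is verified in the tests against an explicit
per-rotation oracle and by the ~1 % empirical false-positive rate on 1000
null units.

The peak offset is `10 ms × (argmax |w − 1| − 100)`, ties broken toward 0
then toward the earlier bin; negative offsets mean movement precedes the
spike. A **positive** swing-gain latency in the generator delays the gain
relative to movement and therefore produces **negative** offsets
(sensory-like lag). Contralateral bias is `b = c_contra / c_ipsi`,
computed separately for front and hind paw pairs; it is undefined (NaN)
when the ipsilateral coupling is 0.

Behavioral selectivity uses a one-sided Wilcoxon rank-sum test of each
class's 500 ms counts against the remainder of the session, BH-corrected
across the six tests per unit at α = 0.05. The class-balanced
Kruskal–Wallis analysis subsamples every class to the smallest class size,
repeats 100 times, and counts pairwise rank-sum rejections (α = 0.05) only
when the omnibus test rejects.

## Population embedding

Counts in 100 ms bins are binarized (≥ 1 spike → 1); time points with
fewer than 15 active units are dropped, and sessions with fewer than 5000
kept points are flagged and excluded from full analyses (tests and small
demos may relax this floor explicitly).

The mutual kNN graph connects i and j iff each is among the other's
k nearest neighbors, `k = max(1, round_half_away(k_fraction · t))`.
Hamming distance is the mismatch fraction of binary columns; distance ties
are broken deterministically by ascending point index (implemented as an
index-proportional epsilon far below the metric's resolution). The
generalized eigenproblem `L v = λ D v` is solved through the symmetric
similarity transform of the random-walk Laplacian: the largest eigenpairs
of `D^{-1/2} W D^{-1/2}` (ARPACK with a fixed all-ones start vector;
dense solver below 64 nodes) give the smallest generalized eigenpairs
after `v = D^{-1/2} u`. The zero-eigenvalue constant eigenvector is
discarded; each remaining dimension's sign is fixed by making its
largest-magnitude entry positive. Graphs are restricted to their largest
connected component (dropped points are recorded and excluded from all
downstream label joins; a warning is recorded when more than 20 % drop).

The full pipeline runs two iterations: Hamming metric with k = 0.5 % to 20
dimensions, then Euclidean metric on those coordinates with k = 7.5 %.
Between the iterations each dimension is winsorized at 4 standard
deviations: occasional extreme eigenvector entries otherwise detach a
handful of points into their own mutual-neighbor clumps whose localized
eigenvectors crowd the global structure out of the final spectrum; the
bulk geometry is unaffected. The second-iteration metric is a config
default and can be overridden.

Landmark Isomap uses the same kNN fraction, a random 10 % landmark subset,
Dijkstra geodesics from the landmarks, classical MDS of the
landmark–landmark geodesics and the standard out-of-sample formula for the
remaining points. PCA operates on non-binarized counts with the same
time-point filter.

Intrinsic dimensionality is the steepest local slope (least-squares fits
over sliding 5-point windows) of log mean-neighbor-count against log
radius on a log-spaced grid. The grid is capped where the average
neighborhood reaches 5 % of the points and radii with fewer than one mean
neighbor are excluded; outside that regime the slope reflects count noise
or manifold wrap-around rather than the scaling exponent. Verified to
±0.5 on a 2-torus and a 1-D curve embedded in 20 dimensions.

## Polytope comparison

Class means are taken over labeled, kept 100 ms bins (a bin inherits its
500 ms snippet's label). Rank concordance ranks, for each class, the other
classes by Euclidean distance (ties broken by canonical class order) and
counts equal ranks across two sessions; its null enumerates all 120
permutations of the five non-reference ranks and all 7260 unordered pairs
(self-pairs included), compared with a two-sample two-sided KS test.

The Jeffries–Matusita test Procrustes-rescales one session's class means
onto the other's (scipy's standardized-frame convention; both distance
matrices are computed in that frame) and evaluates
`d_JM = √Σ_ij (√D^v_ij − √D^w_ij)²`. The null is exhaustive over all 720
label permutations with the identity included, so `p = #(null ≤ observed)
/ 720 ≥ 1/720` and the p-value is exact and bit-reproducible. The test is
directional: `p(v, w)` and `p(w, v)` need not coincide, which is covered
by a test and accepted. With rest excluded, ranks run over four classes
and the JM null has 120 elements.

The somatotopy control rebuilds each class-mean population vector with
unit identities shuffled within their somatotopic region, independently
per class and session, and re-runs the exact JM test for each of 500 (50
in the scaled-down runs) permutations, reporting the mean p-value. In
recording space the Procrustes step requires both sessions to expose the
same number of units; synthetic session pairs are generated accordingly.

## Decoding

The swing–stance decoder takes Gaussian-smoothed (σ = 20 ms) spike counts
in ±400 ms (81 bins of 10 ms per unit, all units) and trains a
fully-connected network with three hidden layers of 500 units, 75 %
dropout, L2 1e-4, Adam (lr 1e-4, batch 64), class-weighted cross-entropy
and early stopping (patience 10 validation evaluations — the patience is
our choice) on a 70/15/15 split; a logistic regression with 3-fold
cross-validated L2 strength on train+validation is the linear baseline.
The network is a compact numpy implementation (`pawcode._mlp`),
deterministic given its seed.

The six-class decoder takes 10 embedding dimensions in 7 consecutive
100 ms bins centered on each labeled snippet (the snippet's five bins plus
one flank on each side; snippets whose context contains a dropped time
point are excluded). Samples are split in temporal order into four equal
folds; four runs rotate them (2 train / 1 validation / 1 test), min–max
normalization statistics come from the training folds only (exposed in
the report and audited by a test), and the network uses 200 units per
layer with 25 % dropout. Reported accuracy is the mean over the four test
folds; all accuracies in the package are balanced (mean per-class)
accuracies.

Cross-session decoding min–max normalizes each session's first four
embedding dimensions to [0, 1], fits a full Procrustes transform
(translation, scale, rotation/reflection) on the alignment classes' mean
vectors only, and trains an RBF-kernel SVM (kernel scale 1 on the
normalized inputs, one-vs-one) on class-balanced subsamples of the train
session's decoding-set points, evaluating on all transformed test-session
decoding-set points over 20 Monte-Carlo repetitions (10 in scaled-down
runs). Alignment and decoding class sets are disjoint by construction and
asserted at run time. Generalization accuracy of a session is its row
mean over test sessions; both the diagonal-inclusive and off-diagonal
variants are reported. The ablation harness re-embeds with 20/40/60/80
random units removed (20 dimensions for the first two, 10 for the last
two) or with one area removed plus random padding to equalize the removed
count, then repeats the generalization run.

## Synthetic study conditions

No generative model of such recordings exists — the generator is an
explicit stand-in whose every distributional choice is a package decision:

- **Behavior**: classes occupy the session as independent segments with
  geometric dwell in 500 ms units; segment-entry probabilities are
  proportional to `class_weights / dwell`, making the stationary time
  fractions equal the configured weights exactly. Defaults: weights
  0.30/0.15/0.10/0.10/0.10/0.25 (step…rest), dwells 2.0/1.5/2.5/4.0/2.0/5.0 s.
- **Gait**: during step (all paws) and rear/turn (front paws, turn bouts
  expressed with probability 0.3), paws swing with duty cycle 0.35 at 1.22
  steps/s; swing speeds are uniform in 1.5–4× the 0.3 mm / 10 ms
  threshold, everything else stays strictly below it. The per-paw gait
  phase re-randomizes at behavior-bout boundaries, emulating inter-paw
  phase drift; without it the paired paws are perfectly anti-phase-locked
  and contralateral bias is unidentifiable.
- **Rates**: each class has a latent archetype
  `z_c = separation · (ẑ_c + offset_c · 1)` (ẑ standard normal /√L,
  latent dimension L = 8, separation 2.0). The population latent state is
  the current class's archetype plus a shared AR(1) fluctuation (sd 1.0,
  τ = 0.5 s) — the temporally continuous trial-to-trial variability that
  makes the population manifold connected. A unit's log rate is a
  Dirichlet(1) mixture of the latent state, centered across classes and
  clipped at ±2.5; baselines are uniform in 2–10 Hz and rates cap at
  50 Hz. The per-class offsets (step +0.20, turn +0.10, drink −0.05,
  groom −0.05, rear +0.15, rest −0.50) act along the all-ones latent
  direction, i.e. as population-wide rate recruitment; they scale with
  `separation`, so separation 0 yields a fully null generator.
- **Swing gains**: contralateral multiplicative gains 1.3 (M2), 1.7 (M1),
  2.2 (S1) with 0.15 log-normal unit jitter; the ipsilateral paw receives
  0.15 of the contralateral gain excess. An optional per-area latency
  delays the gain (positive = spikes follow movement).
- **Sizes**: default 36-minute sessions with 84 units (7 per
  area × hemisphere × limb-region cell) — with fewer units the ≥ 15-active
  filter disproportionately removes rest.
- **Exchangeable classes**: `ArchetypeModel.create(exchangeable_classes
  =True)` constrains archetype deviations to be mean-free, orthogonal to
  the all-ones direction and equal-norm. Classes then have identical
  across-unit rate moments, and only the fine correlation pattern carries
  class identity — the configuration used to show that the somatotopy
  shuffle destroys fine-structure similarity. With unconstrained
  archetypes, class-level moment structure is itself shared across
  subjects and legitimately survives the shuffle.
- **Null subjects**: "no shared code" means independent archetypes *and* a
  permuted class→rate-offset assignment; the offsets are a universal
  physiological feature, and leaving them aligned would leak a
  rest-versus-movement axis across otherwise independent subjects.

What passing tests show — and what they do not: the synthetic data are
Poisson given the latent state, stationary within class, free of electrode
drift, unit splitting, labeling errors and cross-day nonstationarity.
Recovery of planted structure here validates the pipeline's statistics and
implementations (calibrated nulls, exact permutation tests, correct
spectral solutions, leakage-free decoding), not the biological claims on
real recordings.

## Problem sizes

The test suite and `scripts/acceptance.py` run the pipeline on 10–15
minute sessions with 84 units (≥ 5000 kept 100 ms points, preserving the
full-pipeline floor), 5 of the 15 alignment/decoding splits with 10
Monte-Carlo repetitions, 40–50 somatotopy permutations, and reduced
training schedules for the feed-forward decoders (sample subsets of
1500–2000, ≤ 12 epochs). These sizes are the package's scaled-down study
conditions for a single-CPU run; all thresholds and statistical
conventions are identical to the full-size defaults.

## Known limitations

- The mutual-kNN graph can fragment; the largest-component restriction and
  the inter-iteration winsorization are pragmatic guards, and sessions
  where they discard many points should be treated with suspicion (the
  embedding records the dropped fraction).
- The JM permutation test is exact but directional; session-pair matrices
  report each ordered direction separately.
- The numpy feed-forward classifier implements exactly the stated
  architecture but is not a deep-learning framework; very large feature
  sets (many hundreds of units) train slowly on one CPU.
- Procrustes in recording space requires equal unit counts across the two
  sessions; unequal sessions must be compared in an embedding space.
- `swing_gain_by_region` values below 1 suppress firing during swing;
  gain 0 silences a unit during swing, which is itself maximal (anti-)
  coupling, not an absence of modulation — "no modulation" is gain 1.
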