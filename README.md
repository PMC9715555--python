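# pawcode

Analysis pipeline for bilateral sensorimotor-cortex recordings of freely
moving rats: single-unit coupling to paw movements, non-linear
low-dimensional embedding of population activity, cross-session comparison
of behavioral representations, and cross-subject decoding of behavior via
manifold alignment.

## The problem

In unconstrained behavior there is no trial structure, so classical
peri-stimulus averaging cannot relate spikes to movement, and neurons cannot
be tracked across sessions or animals, so single-neuron codes cannot be
compared directly. `pawcode` implements the population-level alternative:

- **STAPSSS** — the *spike-triggered average paw swing–stance status*: each
  paw's horizontal speed is binarized at 0.3 mm / 10 ms into swing (1) and
  stance (0), and the binary series is averaged in ±1 s windows around every
  spike (201 bins of 10 ms), normalized by the waveform mean. Coupling is
  the ratio `c = σ(STAPSSS) / σ₀.₉₉`, where `σ₀.₉₉` is the 0.99 quantile of
  waveform standard deviations over 1000 circularly shifted spike trains;
  `c > 1` marks a significantly coupled unit. The circular shift preserves
  the autocorrelation of both series, so autocorrelated paw movement alone
  cannot create false positives. The contralateral bias is
  `b = c_r / c_l` for left-hemisphere units (and `c_l / c_r` on the right).
- **Laplacian Eigenmaps (LEM)** — population spike counts are binned at
  100 ms, binarized, and time points with < 15 active units dropped. An
  unweighted *mutual* kNN graph (Hamming distance, k = 0.5 % of time points)
  is embedded by solving the generalized eigenproblem `L v = λ D v`
  (random-walk normalized Laplacian); a second iteration rebuilds the graph
  on the 20-dimensional coordinates (Euclidean, k = 7.5 %). The first
  (constant) eigenvector is discarded. Landmark Isomap and PCA (on
  non-binarized counts) are provided as alternative reductions, and
  time-shuffle / neuron-shuffle / time-shift controls destroy the
  time–behavior relationship while preserving marginal statistics.
- **Polytope comparison** — the average population vectors `p^i` of the six
  behavior classes (step, turn, drink, groom, rear, rest) form a polytope
  per session. Two sessions are compared by (i) rank concordance `s_i` of
  their class-distance matrices (exhaustive null over the 5! = 120 rank
  permutations, 7260 unordered pairs) and (ii) the Jeffries–Matusita
  distance `d_JM = √Σ_ij (√D^v_ij − √D^w_ij)²` after Procrustes rescaling,
  with an exact permutation test over all 720 class relabelings.
- **Cross-subject decoding** — the six classes are split into a disjoint
  *alignment set* (fits a full Procrustes transform — translation, scaling,
  rotation, reflection — between two sessions' 4-dimensional embeddings)
  and a *decoding set* (trains an RBF-kernel SVM on class-balanced samples,
  20 Monte-Carlo repetitions). All accuracies are mean per-class (balanced)
  accuracies.

Real recordings of this kind are not redistributable, so the package ships
a first-class synthetic generator (`pawcode.synthetic`): behavior classes as
geometric-dwell segments, shared latent class archetypes mixed per subject,
a smooth AR(1) population latent state, swing-locked rate gains with an
anterior→posterior and contralateral gradient, and inhomogeneous Poisson
spiking. It defines the study conditions under which every claim in the
test suite is verified.

## Worked example

```python
import pawcode as pc

arch = pc.ArchetypeModel.create(seed=0)
config = pc.SessionConfig(duration_s=600.0, seed=11, subject="demo")
session = pc.generate_session(arch, config)

status = pc.binarize_paw(session.paw_velocity[:, 1], paw="front_right")
print(pc.step_statistics(status))

table = pc.stapsss_table(session, seed=0)
print(table.groupby("unit_id")["significant"].any().mean())

emb = pc.lem_pipeline(pc.preprocess_population(session))
rep = pc.behavior_decoder(emb, pc.LabelTrack(session.labels), seed=0)
print(rep.mean_per_class_accuracy)
```

On this 10-minute, 84-unit session the right-front paw moves at 0.73
steps/s with a stance fraction of 0.81 (locomotion bouts occupy part of the
session); 91.7 % of units are significantly coupled to at least one paw;
mean coupling is ordered S1 (1.20) > M1 (1.15) > M2 (0.88) with
contralateral biases well above 1 in all areas, reflecting the planted
anterior→posterior, lateralized gradient; and the six-class behavior
decoder on 10 LEM dimensions reaches 42.9 % balanced accuracy against the
16.66 % chance level.

A command-line interface covers the same pipeline stage by stage:

```bash
pawcode simulate --out data/ --seed 7 --n-subjects 2
pawcode stapsss --session data/session_s0_r0.h5 --out stapsss.csv
pawcode embed --session data/session_s0_r0.h5 --out emb.h5 --method lem
pawcode polytope --session data/session_s0_r0.h5 --session data/session_s1_r0.h5 --out pvals.csv
pawcode align-decode --session data/session_s0_r0.h5 --session data/session_s1_r0.h5 --out gen.csv
```

Every stage writes a JSON run manifest (config, seeds, input hashes) and is
bit-reproducible given `--seed`.

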