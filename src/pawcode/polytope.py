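"""Cross-session comparison of class-mean polytopes.

The average population vectors of the behavior classes define the vertices
of a polytope; two sessions are compared through their class-by-class
Euclidean distance matrices ``D^v`` and ``D^w``. Two statistics are used:

* rank concordance ``s_i``: for each class i, the remaining classes are
  ranked by distance from i in each session; ``s_i`` counts the classes
  holding the same rank in both (0..5 for six classes). Its exhaustive null
  enumerates all 5! = 120 rank permutations and the 7260 unordered pairs of
  permutations.
* the Jeffries-Matusita distance
  ``d_JM = sqrt(sum_ij (sqrt(D^v_ij) - sqrt(D^w_ij))^2)`` after a Procrustes
  rescaling of one session's class means onto the other's, with an exact
  null from all 720 permutations of the class labels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations_with_replacement, permutations
from math import factorial

import numpy as np
from scipy.spatial import procrustes as _scipy_procrustes
from scipy.spatial.distance import pdist, squareform
from scipy.stats import ks_2samp

from .behavior import LabelTrack, labels_on_pop_grid
from .session import CLASSES

JM_ALPHA = 0.05


@dataclass
class ClassMeans:
    """Per-class mean population vectors (polytope vertices)."""

    vectors: dict[str, np.ndarray]
    space: str                          # e.g. "LEM-20" or "recording"
    sample_sizes: dict[str, int] = field(default_factory=dict)

    @property
    def classes(self) -> tuple[str, ...]:
        return tuple(c for c in CLASSES if c in self.vectors)

    def matrix(self, classes: tuple[str, ...] | None = None) -> np.ndarray:
        classes = classes or self.classes
        return np.stack([self.vectors[c] for c in classes])


@dataclass
class PolytopeComparison:
    """Result of comparing two sessions' polytopes."""

    s: dict[str, int]
    d_jm: float
    p_value: float
    n_boot: int
    options: dict = field(default_factory=dict)


def class_means(
    coords: np.ndarray,
    kept_time_index: np.ndarray,
    track: LabelTrack,
    classes: tuple[str, ...] = CLASSES,
    space: str = "embedding",
) -> ClassMeans:
    """Average coordinates over the labeled, kept time points of each class.

    Labels live on the 500 ms grid; each kept 100 ms bin inherits its
    snippet's label.
    """
    grid = labels_on_pop_grid(track)
    labels = grid[kept_time_index]
    vectors, sizes = {}, {}
    missing = []
    for c in classes:
        mask = labels == c
        if not mask.any():
            missing.append(c)
            continue
        vectors[c] = coords[mask].mean(axis=0)
        sizes[c] = int(mask.sum())
    if missing:
        raise ValueError(f"no labeled kept time points for class(es): {missing}")
    return ClassMeans(vectors=vectors, space=space, sample_sizes=sizes)


def distance_matrix(means: ClassMeans | np.ndarray) -> np.ndarray:
    """Symmetric class x class Euclidean distance matrix, zero diagonal."""
    M = means.matrix() if isinstance(means, ClassMeans) else np.asarray(means)
    return squareform(pdist(M))


# ---------------------------------------------------------------------------
# rank concordance
# ---------------------------------------------------------------------------

def _rank_vector(D: np.ndarray, i: int) -> np.ndarray:
    """Rank of every class j != i by distance from i; ties by class order."""
    others = [j for j in range(D.shape[0]) if j != i]
    order = sorted(others, key=lambda j: (D[i, j], j))
    ranks = np.empty(D.shape[0], dtype=int)
    ranks[i] = -1
    for r, j in enumerate(order):
        ranks[j] = r
    return ranks


def rank_concordance(
    Dv: np.ndarray, Dw: np.ndarray, classes: tuple[str, ...] = CLASSES
) -> dict[str, int]:
    """Number of classes holding the same distance rank in both sessions."""
    Dv, Dw = np.asarray(Dv), np.asarray(Dw)
    if np.isnan(Dv).any() or np.isnan(Dw).any():
        raise ValueError("NaN distances")
    n = len(classes)
    s = {}
    for i in range(n):
        rv, rw = _rank_vector(Dv, i), _rank_vector(Dw, i)
        s[classes[i]] = int(
            sum(rv[j] == rw[j] for j in range(n) if j != i)
        )
    return s


def rank_null_distribution(n_classes: int = 6) -> np.ndarray:
    """Exhaustive null of the concordance statistic.

    All permutations of the ``n_classes - 1`` non-reference ranks are
    paired (unordered, self-pairs included); for six classes that is 120
    permutations and 7260 pairs. The expected concordance of a random pair
    is 1 (the fixed-point count of a random permutation).
    """
    if n_classes not in (5, 6):
        raise ValueError("n_classes must be 5 or 6")
    m = n_classes - 1
    perms = [np.array(p) for p in permutations(range(m))]
    return np.array(
        [
            int(np.sum(a == b))
            for a, b in combinations_with_replacement(perms, 2)
        ]
    )


def rank_ks_test(observed_s: np.ndarray, n_classes: int = 6):
    """Two-sample two-sided KS test of observed concordances vs the null."""
    null = rank_null_distribution(n_classes)
    return ks_2samp(np.asarray(observed_s), null)


# ---------------------------------------------------------------------------
# Jeffries-Matusita similarity
# ---------------------------------------------------------------------------

def jm_distance(Dv: np.ndarray, Dw: np.ndarray) -> float:
    """``sqrt(sum_ij (sqrt(Dv_ij) - sqrt(Dw_ij))^2)`` over all index pairs."""
    return float(np.sqrt(np.sum((np.sqrt(Dv) - np.sqrt(Dw)) ** 2)))


def _procrustes_distances(V: np.ndarray, W: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Distance matrices after Procrustes-rescaling ``W`` onto ``V``.

    Both configurations are reported in the standardized frame of ``V``;
    the transform family is translation + scaling + rotation/reflection.
    """
    m1, m2, _ = _scipy_procrustes(V, W)
    return squareform(pdist(m1)), squareform(pdist(m2))


def jm_similarity_test(
    means_v: ClassMeans,
    means_w: ClassMeans,
    exclude_rest: bool = False,
) -> PolytopeComparison:
    """Exact label-permutation test of polytope similarity.

    The null recomputes ``d_JM`` for every permutation of session w's class
    labels (720 for six classes, exhaustive, identity included), so
    ``p = #(null <= observed) / 720`` with minimum 1/720.
    """
    classes = tuple(c for c in CLASSES if not (exclude_rest and c == "rest"))
    for m in (means_v, means_w):
        missing = set(classes) - set(m.vectors)
        if missing:
            raise ValueError(f"missing class means: {sorted(missing)}")
    if len(classes) < 3:
        raise ValueError("Procrustes underdetermined with fewer than 3 classes")
    V = means_v.matrix(classes)
    W = means_w.matrix(classes)
    Dv, Dw = _procrustes_distances(V, W)
    observed = jm_distance(Dv, Dw)
    s = rank_concordance(Dv, Dw, classes)

    n = len(classes)
    null = np.empty(factorial(n))
    for idx, perm in enumerate(permutations(range(n))):
        Dv_p, Dw_p = _procrustes_distances(V, W[list(perm)])
        null[idx] = jm_distance(Dv_p, Dw_p)
    p = float(np.sum(null <= observed + 1e-12) / len(null))
    return PolytopeComparison(
        s=s,
        d_jm=observed,
        p_value=p,
        n_boot=len(null),
        options={"exclude_rest": exclude_rest, "space": means_v.space},
    )


# ---------------------------------------------------------------------------
# somatotopy shuffle control
# ---------------------------------------------------------------------------

@dataclass
class SomatotopyShuffleResult:
    mean_p: float
    significant: bool          # mean p below alpha
    p_unshuffled: float
    n_perm: int


def population_class_means(
    session, min_active: int = 15, space: str = "recording"
) -> ClassMeans:
    """Class-mean binarized population vectors in recording space."""
    from .manifold import preprocess_population

    bpm = preprocess_population(session, min_active=min_active)
    return class_means(
        bpm.matrix.T.astype(float),
        bpm.kept_time_index,
        LabelTrack(session.labels),
        space=space,
    )


def _shuffle_within_region(
    means: ClassMeans, regions: np.ndarray, rng: np.random.Generator
) -> ClassMeans:
    """Permute unit identities within each somatotopic region, per class."""
    vectors = {}
    for c, vec in means.vectors.items():
        out = vec.copy()
        for r in np.unique(regions):
            idx = np.nonzero(regions == r)[0]
            if len(idx) > 1:
                out[idx] = vec[rng.permutation(idx)]
        vectors[c] = out
    return ClassMeans(vectors, means.space, dict(means.sample_sizes))


def somatotopy_shuffle_test(
    session_v,
    session_w,
    n_perm: int = 500,
    seed: int | None = 0,
    exclude_rest: bool = False,
    alpha: float = JM_ALPHA,
) -> SomatotopyShuffleResult:
    """Does polytope similarity survive destroying within-region unit identity?

    For each of ``n_perm`` permutations, both sessions' class-mean
    population vectors are rebuilt with unit identities shuffled within
    their somatotopic region (independently per class), the exact
    Jeffries-Matusita label-permutation test is re-run, and the average
    p-value over permutations is reported. Similarity that is a mere
    byproduct of region-level somatotopy survives the shuffle; fine-grained
    unit-level structure does not.
    """
    regions = {}
    for name, sess in (("v", session_v), ("w", session_w)):
        reg = sess.units["region"].to_numpy()
        if np.any(reg == "unknown"):
            raise ValueError(
                f"session {name} has units with unknown somatotopic region"
            )
        regions[name] = reg
        for r in np.unique(reg):
            if np.sum(reg == r) == 1:
                warnings.warn(
                    f"region {r!r} has a single unit; shuffle is the identity",
                    stacklevel=2,
                )
    means_v = population_class_means(session_v)
    means_w = population_class_means(session_w)
    p_unshuffled = jm_similarity_test(
        means_v, means_w, exclude_rest=exclude_rest
    ).p_value
    rng = np.random.default_rng(seed)
    pvals = np.empty(n_perm)
    for b in range(n_perm):
        mv = _shuffle_within_region(means_v, regions["v"], rng)
        mw = _shuffle_within_region(means_w, regions["w"], rng)
        pvals[b] = jm_similarity_test(mv, mw, exclude_rest=exclude_rest).p_value
    mean_p = float(pvals.mean())
    return SomatotopyShuffleResult(
        mean_p=mean_p,
        significant=mean_p < alpha,
        p_unshuffled=float(p_unshuffled),
        n_perm=n_perm,
    )
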