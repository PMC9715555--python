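"""Population preprocessing and low-dimensional embedding.

Population activity is binned at 100 ms, binarized (>= 1 spike -> 1), and
time points with fewer than 15 active units are dropped. Embeddings follow
the two-iteration Laplacian-Eigenmaps recipe: an unweighted mutual kNN graph
(Hamming distance, k = 0.5% of time points) is embedded to 20 dimensions by
solving the generalized eigenproblem ``L v = lambda D v`` (the random-walk
normalized Laplacian); a second graph built on those coordinates (Euclidean,
k = 7.5%) is embedded again. The eigenvector of the zero eigenvalue is
constant and discarded; the remaining dimensions are ordered by eigenvalue.
Landmark Isomap and PCA (on non-binarized counts) serve as alternative
reductions, and shuffle/shift controls destroy the time-label relationship
while preserving marginal statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components, dijkstra
from scipy.sparse.linalg import eigsh

from .session import POP_BIN_S, Session

MIN_ACTIVE_DEFAULT = 15
MIN_TIME_POINTS = 5000
LEM_DIMS = 20
K_FRACTION_IT1 = 0.005
K_FRACTION_IT2 = 0.075
#: deterministic tie-break: distances get +index * _TIE_EPS
_TIE_EPS = 1e-10


@dataclass
class BinaryPopulationMatrix:
    """Binarized population activity, units x kept 100 ms time points."""

    matrix: np.ndarray                # (n_units, t_kept) uint8
    kept_time_index: np.ndarray       # kept column -> original 100 ms bin
    min_active: int
    n_total_bins: int
    flagged: bool = False             # too few kept points for full analyses


@dataclass
class NeighborGraph:
    """Unweighted mutual kNN graph with its Laplacian ingredients."""

    W: sp.csr_matrix                  # symmetric 0/1 adjacency, zero diagonal
    k: int
    metric: str
    distances: sp.csr_matrix | None = None  # directed kNN distances (Isomap)

    @property
    def degrees(self) -> np.ndarray:
        return np.asarray(self.W.sum(axis=1)).ravel()

    def laplacian(self) -> sp.csr_matrix:
        return sp.diags(self.degrees) - self.W


@dataclass
class Embedding:
    """Time points embedded in a low-dimensional space."""

    coords: np.ndarray                # (t, d)
    eigenvalues: np.ndarray           # ascending, constant eigenpair removed
    kept_time_index: np.ndarray       # row -> original 100 ms bin
    method: str                       # LEM | Isomap | PCA
    params: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def preprocess_population(
    session: Session,
    min_active: int = MIN_ACTIVE_DEFAULT,
    bin_s: float = POP_BIN_S,
    min_time_points: int = MIN_TIME_POINTS,
) -> BinaryPopulationMatrix:
    """Bin at 100 ms, binarize, and keep columns with enough active units."""
    if session.n_units < 1:
        raise ValueError("session has no units")
    counts = session.spike_counts(bin_s)
    binary = (counts >= 1).astype(np.uint8)
    active = binary.sum(axis=0)
    keep = np.nonzero(active >= min_active)[0]
    flagged = len(keep) < min_time_points
    return BinaryPopulationMatrix(
        matrix=binary[:, keep],
        kept_time_index=keep,
        min_active=min_active,
        n_total_bins=binary.shape[1],
        flagged=flagged,
    )


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5))


def _knn_indices(
    X: np.ndarray, k: int, metric: str, chunk: int = 1024
) -> np.ndarray:
    """Indices of the k nearest neighbors per row (self excluded).

    Distance ties are broken by ascending point index via an epsilon ramp
    that is far below the metric's resolution.
    """
    t = X.shape[0]
    if k >= t:
        raise ValueError(f"k={k} must be smaller than the number of points {t}")
    Xf = X.astype(np.float32)
    if metric == "hamming":
        ones = 1.0 - Xf
    elif metric != "euclidean":
        raise ValueError(f"unknown metric: {metric}")
    sq = (Xf**2).sum(axis=1) if metric == "euclidean" else None
    ramp = (_TIE_EPS * np.arange(t)).astype(np.float64)
    out = np.empty((t, k), dtype=np.int64)
    for start in range(0, t, chunk):
        stop = min(start + chunk, t)
        if metric == "hamming":
            mism = Xf[start:stop] @ ones.T + ones[start:stop] @ Xf.T
            D = mism.astype(np.float64) / X.shape[1]
        else:
            D = sq[start:stop, None] - 2.0 * (Xf[start:stop] @ Xf.T) + sq[None, :]
            D = np.sqrt(np.maximum(D, 0.0, dtype=np.float64))
        D += ramp[None, :]
        rows = np.arange(start, stop)
        D[rows - start, rows] = np.inf
        part = np.argpartition(D, k - 1, axis=1)[:, :k]
        part_d = np.take_along_axis(D, part, axis=1)
        order = np.argsort(part_d, axis=1, kind="stable")
        out[start:stop] = np.take_along_axis(part, order, axis=1)
    return out


def mutual_knn_graph(
    X: np.ndarray,
    k_fraction: float,
    metric: str = "hamming",
    keep_distances: bool = False,
) -> NeighborGraph:
    """Unweighted mutual kNN graph on the rows of ``X``.

    ``k = max(1, round(k_fraction * t))`` with round-half-away-from-zero;
    an edge (i, j) exists iff i is among j's k nearest neighbors and vice
    versa.
    """
    t = X.shape[0]
    k = max(1, _round_half_away(k_fraction * t))
    nbrs = _knn_indices(X, k, metric)
    rows = np.repeat(np.arange(t), k)
    cols = nbrs.ravel()
    directed = sp.csr_matrix(
        (np.ones(t * k, dtype=np.uint8), (rows, cols)), shape=(t, t)
    )
    W = directed.minimum(directed.T).astype(np.float64)
    W.setdiag(0)
    W.eliminate_zeros()
    dist = None
    if keep_distances:
        if metric == "hamming":
            d = (X[rows] != X[cols]).mean(axis=1)
        else:
            d = np.linalg.norm(X[rows] - X[cols], axis=1)
        dist = sp.csr_matrix((d, (rows, cols)), shape=(t, t))
        dist = dist.maximum(dist.T)
    return NeighborGraph(W=W.tocsr(), k=k, metric=metric, distances=dist)


# ---------------------------------------------------------------------------
# spectral embedding
# ---------------------------------------------------------------------------

def _largest_component(W: sp.csr_matrix) -> np.ndarray:
    n_comp, labels = connected_components(W, directed=False)
    if n_comp == 1:
        return np.arange(W.shape[0])
    sizes = np.bincount(labels)
    biggest = int(np.argmax(sizes))
    warnings.warn(
        f"graph has {n_comp} components; restricting to the largest "
        f"({sizes[biggest]}/{W.shape[0]} points)",
        stacklevel=3,
    )
    return np.nonzero(labels == biggest)[0]


def _fix_signs(vectors: np.ndarray) -> np.ndarray:
    """Make each eigenvector's largest-magnitude entry positive."""
    idx = np.argmax(np.abs(vectors), axis=0)
    signs = np.sign(vectors[idx, np.arange(vectors.shape[1])])
    signs[signs == 0] = 1.0
    return vectors * signs


def spectral_embed(
    graph: NeighborGraph,
    d: int,
    kept_time_index: np.ndarray | None = None,
) -> Embedding:
    """Embed a neighbor graph via ``L v = lambda D v``.

    The generalized problem is solved through the symmetric similarity
    transform of the random-walk Laplacian: the ``d + 1`` largest eigenpairs
    of the normalized adjacency ``D^-1/2 W D^-1/2`` give the ``d + 1``
    smallest of the generalized problem; eigenvectors are back-transformed,
    the constant one discarded, and signs fixed so the largest-magnitude
    entry of each dimension is positive.
    """
    comp = _largest_component(graph.W)
    W = graph.W[np.ix_(comp, comp)]
    n = W.shape[0]
    deg = np.asarray(W.sum(axis=1)).ravel()
    if n < d + 2:
        raise ValueError(f"component of size {n} too small for d={d}")
    if np.any(deg == 0):
        raise ValueError("isolated vertices after component restriction")
    d_isqrt = 1.0 / np.sqrt(deg)
    N = sp.diags(d_isqrt) @ W @ sp.diags(d_isqrt)
    if n < max(64, 2 * (d + 2)):  # ARPACK needs k < ncv <= n; go dense
        vals_all, vecs_all = np.linalg.eigh(N.toarray())
        vals = vals_all[-(d + 1):]
        vecs = vecs_all[:, -(d + 1):]
    else:
        v0 = np.ones(n)
        vals, vecs = eigsh(
            N, k=d + 1, which="LA", v0=v0,
            ncv=min(n - 1, max(4 * (d + 1), 60)),
        )
    # ascending in N; reverse so the generalized eigenvalues ascend
    lam = 1.0 - vals[::-1]
    U = vecs[:, ::-1]
    V = U * d_isqrt[:, None]
    # drop the (near-)zero eigenvalue and its constant eigenvector
    lam, V = lam[1:], V[:, 1:]
    V = _fix_signs(V)
    if kept_time_index is None:
        kept_time_index = np.arange(graph.W.shape[0])
    dropped = 1.0 - n / graph.W.shape[0]
    params = {"k": graph.k, "metric": graph.metric, "dropped_fraction": dropped}
    if dropped > 0.2:
        params["warning"] = "component restriction dropped > 20% of points"
        warnings.warn(params["warning"], stacklevel=2)
    return Embedding(
        coords=V,
        eigenvalues=np.maximum(lam, 0.0),
        kept_time_index=np.asarray(kept_time_index)[comp],
        method="LEM",
        params=params,
    )


def lem_pipeline(
    bpm: BinaryPopulationMatrix,
    dims: int = LEM_DIMS,
    k_fraction_1: float = K_FRACTION_IT1,
    k_fraction_2: float = K_FRACTION_IT2,
    metric_2: str = "euclidean",
    enforce_floor: bool = True,
    winsor_sd: float = 4.0,
    min_time_points: int = MIN_TIME_POINTS,
) -> Embedding:
    """Two-iteration LEM: Hamming graph, embed, rebuild graph, embed again.

    Before the second graph is built, each first-iteration dimension is
    winsorized at ``winsor_sd`` standard deviations: stray extreme
    eigenvector entries otherwise detach a handful of points into their own
    mutual-neighbor clumps, whose localized eigenvectors would crowd out
    the global structure in the final embedding. The bulk geometry is
    unaffected.
    """
    t = bpm.matrix.shape[1]
    if enforce_floor and t < min_time_points:
        raise ValueError(
            f"only {t} kept time points (< {min_time_points}); "
            "session excluded from full analyses"
        )
    X1 = bpm.matrix.T
    g1 = mutual_knn_graph(X1, k_fraction_1, metric="hamming")
    emb1 = spectral_embed(g1, dims, kept_time_index=bpm.kept_time_index)
    X2 = emb1.coords
    if winsor_sd:
        mu, sd = X2.mean(axis=0), X2.std(axis=0)
        X2 = np.clip(X2, mu - winsor_sd * sd, mu + winsor_sd * sd)
    g2 = mutual_knn_graph(X2, k_fraction_2, metric=metric_2)
    emb2 = spectral_embed(g2, dims, kept_time_index=emb1.kept_time_index)
    emb2.params = {
        "iteration_1": emb1.params,
        "iteration_2": {k: v for k, v in emb2.params.items()},
        "min_active": bpm.min_active,
    }
    return emb2


# ---------------------------------------------------------------------------
# controls
# ---------------------------------------------------------------------------

CONTROL_MODES = ("time_shuffle", "neuron_shuffle", "time_shift")


def control_transforms(
    bpm: BinaryPopulationMatrix, mode: str, seed: int | None = 0
) -> BinaryPopulationMatrix:
    """Shuffle/shift controls that break the time-label relationship.

    ``time_shuffle`` permutes columns globally (row sums and the column
    multiset preserved); ``neuron_shuffle`` permutes each row independently
    (row sums preserved, column structure destroyed); ``time_shift``
    circularly rotates each row by an independent random offset.
    """
    rng = np.random.default_rng(seed)
    m = bpm.matrix.copy()
    t = m.shape[1]
    if mode == "time_shuffle":
        m = m[:, rng.permutation(t)]
    elif mode == "neuron_shuffle":
        for i in range(m.shape[0]):
            m[i] = m[i, rng.permutation(t)]
    elif mode == "time_shift":
        for i in range(m.shape[0]):
            m[i] = np.roll(m[i], int(rng.integers(0, t)))
    else:
        raise ValueError(f"unknown control mode: {mode}")
    return BinaryPopulationMatrix(
        matrix=m,
        kept_time_index=bpm.kept_time_index.copy(),
        min_active=bpm.min_active,
        n_total_bins=bpm.n_total_bins,
        flagged=bpm.flagged,
    )


# ---------------------------------------------------------------------------
# intrinsic dimensionality
# ---------------------------------------------------------------------------

def estimate_dimensionality(
    coords: np.ndarray,
    n_radii: int = 40,
    max_points: int = 2000,
) -> float:
    """Neighbor-count slope estimate of intrinsic dimensionality.

    The mean number of neighbors within radius r scales as ``r^d`` on a
    d-dimensional manifold; the estimate is the steepest local slope of
    ``log N(r)`` against ``log r``, with slopes fitted over sliding 5-point
    windows of a log-spaced radius grid. Scale-invariant by construction.
    """
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if n < 500:
        raise ValueError("need at least 500 points")
    if n > max_points:
        step = n / max_points
        coords = coords[(np.arange(max_points) * step).astype(int)]
        n = coords.shape[0]
    from scipy.spatial.distance import pdist

    d = np.sort(pdist(coords))
    d = d[d > 0]
    # scaling regime: stop once the average neighborhood holds 5% of the
    # points — beyond that, global manifold structure (wrap-around,
    # boundaries) distorts the growth exponent
    r_hi = d[min(len(d) - 1, int(0.05 * n * n / 2))]
    radii = np.geomspace(np.quantile(d, 0.001), r_hi, n_radii)
    # mean neighbors within r = 2 * (#pairs <= r) / n; radii with fewer
    # than one neighbor on average are count-noise dominated and excluded
    counts = 2.0 * np.searchsorted(d, radii, side="right") / n
    valid = counts >= 1.0
    radii, counts = radii[valid], counts[valid]
    if len(radii) < 5:
        raise ValueError("too few radii with non-zero neighbor counts")
    logr, logn = np.log(radii), np.log(counts)
    slopes = [
        np.polyfit(logr[i : i + 5], logn[i : i + 5], 1)[0]
        for i in range(len(radii) - 4)
    ]
    return float(np.max(slopes))


# ---------------------------------------------------------------------------
# alternative embeddings
# ---------------------------------------------------------------------------

def isomap_embed(
    bpm: BinaryPopulationMatrix,
    d: int,
    k_fraction: float = K_FRACTION_IT1,
    landmark_fraction: float = 0.1,
    seed: int | None = 0,
) -> Embedding:
    """Landmark Isomap on the binarized population matrix.

    Geodesic distances are shortest paths on the Hamming kNN graph,
    computed from a random 10% landmark subset; landmark coordinates come
    from classical MDS of the landmark geodesics and the remaining points
    are placed by the standard landmark out-of-sample formula.
    """
    X = bpm.matrix.T.astype(np.float64)
    t = X.shape[0]
    g = mutual_knn_graph(X, k_fraction, metric="hamming", keep_distances=True)
    comp = _largest_component(g.distances.maximum(g.distances.T))
    if len(comp) < t:
        warnings.warn(
            f"geodesic graph disconnected; using largest component "
            f"({len(comp)}/{t})",
            stacklevel=2,
        )
    D = g.distances[np.ix_(comp, comp)]
    n = len(comp)
    rng = np.random.default_rng(seed)
    n_land = max(d + 1, _round_half_away(landmark_fraction * n))
    landmarks = np.sort(rng.choice(n, size=min(n_land, n), replace=False))
    geo = dijkstra(D, directed=False, indices=landmarks)
    if np.isinf(geo).any():
        finite = ~np.isinf(geo).any(axis=0)
        warnings.warn("unreachable points dropped from Isomap", stacklevel=2)
        keep_local = np.nonzero(finite)[0]
        geo = geo[:, keep_local]
        land_pos = np.searchsorted(keep_local, landmarks)
        comp = comp[keep_local]
        landmarks = land_pos
        n = len(comp)
    sq = geo**2
    sq_ll = sq[:, landmarks]
    L = len(landmarks)
    J = np.eye(L) - np.ones((L, L)) / L
    B = -0.5 * J @ sq_ll @ J
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1][:d]
    vals_d = np.maximum(vals[order], 0.0)
    vecs_d = vecs[:, order]
    pos = vals_d > 1e-12
    coords_land = vecs_d * np.sqrt(vals_d)
    # out-of-sample placement for all points
    mean_sq = sq_ll.mean(axis=1)
    pseudo = np.zeros_like(vecs_d)
    pseudo[:, pos] = vecs_d[:, pos] / np.sqrt(vals_d[pos])
    coords = 0.5 * (mean_sq[None, :] - sq.T) @ pseudo
    coords[landmarks] = coords_land
    coords = _fix_signs(coords)
    return Embedding(
        coords=coords,
        eigenvalues=vals_d,
        kept_time_index=bpm.kept_time_index[comp],
        method="Isomap",
        params={"k": g.k, "n_landmarks": L, "seed": seed},
    )


def pca_embed(
    session: Session,
    d: int,
    min_active: int = MIN_ACTIVE_DEFAULT,
    bin_s: float = POP_BIN_S,
) -> Embedding:
    """PCA on non-binarized 100 ms counts, same time-point filter as LEM."""
    counts = session.spike_counts(bin_s).astype(np.float64)
    active = (counts >= 1).sum(axis=0)
    keep = np.nonzero(active >= min_active)[0]
    X = counts[:, keep].T
    Xc = X - X.mean(axis=0)
    cov = Xc.T @ Xc / max(len(X) - 1, 1)
    vals, vecs = np.linalg.eigh(cov)
    order = np.argsort(vals)[::-1][:d]
    vecs = _fix_signs(vecs[:, order])
    return Embedding(
        coords=Xc @ vecs,
        eigenvalues=np.maximum(vals[order], 0.0),
        kept_time_index=keep,
        method="PCA",
        params={"min_active": min_active},
    )


def area_subset_embedding(
    session: Session,
    area: str,
    n_units: int = 20,
    d: int = 6,
    seed: int | None = 0,
    min_active: int = MIN_ACTIVE_DEFAULT,
    enforce_floor: bool = False,
) -> Embedding | None:
    """LEM on a random fixed-size unit subset of one area.

    Time points are selected with the full-population activity filter, then
    the population matrix is restricted to the sampled units, so subsets of
    different areas see identical time points. Returns ``None`` (with a
    warning) when the area has fewer than ``n_units`` units. ``d`` counts
    the constant dimension, so ``d = 6`` yields 5 usable dimensions.
    """
    idx = np.nonzero((session.units["area"] == area).to_numpy())[0]
    if len(idx) < n_units:
        warnings.warn(
            f"area {area} has {len(idx)} < {n_units} units; skipped",
            stacklevel=2,
        )
        return None
    rng = np.random.default_rng(seed)
    chosen = np.sort(rng.choice(idx, size=n_units, replace=False))
    bpm = preprocess_population(session, min_active=min_active)
    sub = BinaryPopulationMatrix(
        matrix=bpm.matrix[chosen],
        kept_time_index=bpm.kept_time_index,
        min_active=bpm.min_active,
        n_total_bins=bpm.n_total_bins,
        flagged=bpm.flagged,
    )
    emb = lem_pipeline(sub, dims=d - 1, enforce_floor=enforce_floor)
    emb.params["sampled_units"] = chosen.tolist()
    emb.params["area"] = area
    return emb


def minmax_normalize(coords: np.ndarray) -> np.ndarray:
    """Scale each dimension to [0, 1] over all time points."""
    lo = coords.min(axis=0)
    span = coords.max(axis=0) - lo
    span[span == 0] = 1.0
    return (coords - lo) / span
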