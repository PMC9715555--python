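"""Within-session and cross-session decoding of behavior.

Two within-session decoders mirror the analysis pipeline: a feed-forward
network predicting the swing-stance status of the right front paw from
Gaussian-smoothed spike windows (+-400 ms, 81 bins of 10 ms per unit), and
a six-class behavior decoder on 10 embedding dimensions in 7 consecutive
100 ms bins. Cross-session and cross-subject decoding splits the six
classes into a disjoint *alignment set* (used to fit a full Procrustes
transform between the two sessions' 4-dimensional embeddings) and a
*decoding set* (used to train/test an RBF-kernel SVM); no sample of the
decoding classes ever enters the alignment. All reported accuracies are
mean per-class (balanced) accuracies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from sklearn.svm import SVC

from ._mlp import FeedForwardClassifier, balanced_accuracy
from .behavior import LabelTrack, binarize_paw, labels_on_pop_grid
from .manifold import minmax_normalize
from .session import CLASSES, PAWS, UNLABELED, VEL_BIN_S, Session

WINDOW_BINS_10MS = 40           # +-400 ms
FEATURE_BINS = 2 * WINDOW_BINS_10MS + 1   # 81
SMOOTH_SIGMA_BINS = 2           # 20 ms at 10 ms bins
CONTEXT_BINS_100MS = 7          # snippet's 5 bins + 1 flank each side
ALIGN_DIMS = 4
DECODER_DIMS = 10


@dataclass
class DecodingReport:
    """Balanced-accuracy report of one decoding experiment."""

    mean_per_class_accuracy: float          # percent
    per_class_recalls: dict[str, float]     # percent
    train_session: str = ""
    test_session: str = ""
    split_id: str = ""
    n_runs: int = 1
    extras: dict = field(default_factory=dict)


def _report(y_true, y_pred, classes, **kwargs) -> DecodingReport:
    recalls = {}
    for c in classes:
        mask = y_true == c
        if mask.any():
            recalls[c] = 100.0 * float(np.mean(y_pred[mask] == c))
    return DecodingReport(
        mean_per_class_accuracy=float(np.mean(list(recalls.values()))),
        per_class_recalls=recalls,
        **kwargs,
    )


# ---------------------------------------------------------------------------
# class splits
# ---------------------------------------------------------------------------

def class_splits(n_align: int) -> list[tuple[tuple[str, ...], tuple[str, ...]]]:
    """All partitions of the six classes into alignment and decoding sets.

    ``n_align = 4`` gives 15 splits, ``n_align = 3`` gives 20.
    """
    if n_align not in (3, 4, 5):
        raise ValueError("n_align must be 3, 4 or 5")
    splits = []
    for align in combinations(CLASSES, n_align):
        decode = tuple(c for c in CLASSES if c not in align)
        splits.append((align, decode))
    return splits


# ---------------------------------------------------------------------------
# swing-stance decoding from spike trains
# ---------------------------------------------------------------------------

def feature_windows(
    session: Session,
    centers: np.ndarray,
    sigma_bins: float = SMOOTH_SIGMA_BINS,
) -> np.ndarray:
    """Gaussian-smoothed +-400 ms spike-count windows, flattened per sample."""
    counts = session.spike_counts(VEL_BIN_S).astype(np.float32)
    smoothed = gaussian_filter1d(counts, sigma=sigma_bins, axis=1)
    offsets = np.arange(-WINDOW_BINS_10MS, WINDOW_BINS_10MS + 1)
    windows = smoothed[:, centers[:, None] + offsets]      # (n_units, n, 81)
    return windows.transpose(1, 0, 2).reshape(len(centers), -1)


def swing_decoder(
    session: Session,
    seed: int = 0,
    paw: str = "front_right",
    max_samples: int = 6000,
    mlp_kwargs: dict | None = None,
    with_baseline: bool = True,
) -> DecodingReport:
    """Two-class swing-stance decoder from all units' spike windows.

    A feed-forward network (three hidden layers of 500 units, 75% dropout,
    L2 1e-4, Adam lr 1e-4, batch 64, class-weighted loss, early stopping)
    is trained on a 70/15/15 train/validation/test split; a logistic
    regression with 3-fold cross-validated L2 strength on train+validation
    provides the linear baseline.
    """
    status = binarize_paw(
        session.paw_velocity[:, PAWS.index(paw)], paw=paw
    ).values
    T = len(status)
    valid = np.arange(WINDOW_BINS_10MS, T - WINDOW_BINS_10MS)
    rng = np.random.default_rng([seed, 7])
    if len(valid) > max_samples:
        valid = np.sort(rng.choice(valid, size=max_samples, replace=False))
    X = feature_windows(session, valid)
    y = status[valid].astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("only one swing-stance class present")

    idx = rng.permutation(len(y))
    n_train = int(0.70 * len(y))
    n_val = int(0.15 * len(y))
    tr, va, te = np.split(idx, [n_train, n_train + n_val])
    for part, name in ((tr, "train"), (va, "validation"), (te, "test")):
        if len(np.unique(y[part])) < 2:
            raise ValueError(f"class missing from {name} split")

    kwargs = dict(
        hidden=(500, 500, 500), dropout=0.75, l2=1e-4, lr=1e-4,
        batch_size=64, max_epochs=60, patience=10, seed=seed,
    )
    kwargs.update(mlp_kwargs or {})
    clf = FeedForwardClassifier(**kwargs)
    clf.fit(X[tr], y[tr], X[va], y[va])
    y_pred = clf.predict(X[te])
    report = _report(
        y[te], y_pred, (0, 1),
        train_session=str(session.meta.get("seed", "")),
        split_id="swing",
    )
    report.per_class_recalls = {
        "stance": report.per_class_recalls.get(0, np.nan),
        "swing": report.per_class_recalls.get(1, np.nan),
    }
    if with_baseline:
        from sklearn.linear_model import LogisticRegressionCV

        base = LogisticRegressionCV(
            Cs=5, cv=3, class_weight="balanced", max_iter=300,
            random_state=seed,
        )
        trval = np.concatenate([tr, va])
        base.fit(X[trval], y[trval])
        report.extras["baseline_accuracy"] = 100.0 * balanced_accuracy(
            y[te], base.predict(X[te]), 2
        )
    return report


# ---------------------------------------------------------------------------
# six-class decoding from embeddings
# ---------------------------------------------------------------------------

def embedding_samples(
    embedding, track: LabelTrack, dims: int = DECODER_DIMS
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-snippet feature vectors: ``dims`` x 7 consecutive 100 ms bins.

    The 7-bin context is centered on the labeled snippet (its five bins
    plus one flanking bin on each side); snippets whose context includes a
    dropped time point are excluded. Returns (X, y, snippet_index).
    """
    coords = embedding.coords[:, :dims]
    n_bins_total = len(track.labels) * 5
    full = np.full((n_bins_total, coords.shape[1]), np.nan)
    full[embedding.kept_time_index] = coords
    labels = np.asarray(track.labels)
    X, y, snip = [], [], []
    for s, lab in enumerate(labels):
        if lab == UNLABELED:
            continue
        start = s * 5 - 1
        stop = start + CONTEXT_BINS_100MS
        if start < 0 or stop > n_bins_total:
            continue
        window = full[start:stop]
        if np.isnan(window).any():
            continue
        X.append(window.ravel())
        y.append(lab)
        snip.append(s)
    if not X:
        raise ValueError("no usable labeled snippets")
    return np.asarray(X), np.asarray(y), np.asarray(snip)


def behavior_decoder(
    embedding,
    track: LabelTrack,
    seed: int = 0,
    dims: int = DECODER_DIMS,
    mlp_kwargs: dict | None = None,
) -> DecodingReport:
    """Six-class behavior decoder on embedding coordinates.

    Samples are split in temporal order into four equal folds; four runs
    rotate the folds (2 train / 1 validation / 1 test). Min-max
    normalization statistics come from the training folds only. The
    network uses three hidden layers of 200 units with 25% dropout and
    class-weighted loss; reported accuracy is the mean over the four test
    folds.
    """
    X, y, _ = embedding_samples(embedding, track, dims=dims)
    classes = [c for c in CLASSES if np.any(y == c)]
    counts = {c: int(np.sum(y == c)) for c in classes}
    if min(counts.values()) < 4:
        warnings.warn(
            f"class with < 4 samples: {counts}; folds may miss classes",
            stacklevel=2,
        )
    folds = np.array_split(np.arange(len(y)), 4)
    kwargs = dict(
        hidden=(200, 200, 200), dropout=0.25, l2=1e-4, lr=1e-4,
        batch_size=64, max_epochs=120, patience=10,
    )
    kwargs.update(mlp_kwargs or {})
    accs, recalls, norm_bounds = [], [], []
    for run in range(4):
        te = folds[run]
        va = folds[(run + 1) % 4]
        tr = np.concatenate([folds[(run + 2) % 4], folds[(run + 3) % 4]])
        lo = X[tr].min(axis=0)
        span = X[tr].max(axis=0) - lo
        span[span == 0] = 1.0
        norm_bounds.append((lo, span))
        norm = lambda Z: (Z - lo) / span  # noqa: E731
        clf = FeedForwardClassifier(seed=[seed, run], **kwargs)
        clf.fit(norm(X[tr]), y[tr], norm(X[va]), y[va])
        y_pred = clf.predict(norm(X[te]))
        rep = _report(y[te], y_pred, classes)
        accs.append(rep.mean_per_class_accuracy)
        recalls.append(rep.per_class_recalls)
    mean_recalls = {
        c: float(np.mean([r[c] for r in recalls if c in r])) for c in classes
    }
    return DecodingReport(
        mean_per_class_accuracy=float(np.mean(accs)),
        per_class_recalls=mean_recalls,
        split_id="six-class",
        n_runs=4,
        extras={
            "per_run_accuracy": accs,
            "class_counts": counts,
            "norm_bounds": norm_bounds,  # train-fold min/span per run
        },
    )


# ---------------------------------------------------------------------------
# Procrustes alignment
# ---------------------------------------------------------------------------

@dataclass
class AlignmentTransform:
    """Full Procrustes map (translation, scaling, rotation/reflection).

    Maps points from the target session's space onto the source session's:
    ``x -> (x - target_mean) @ Q * scale + source_mean``.
    """

    source_mean: np.ndarray
    target_mean: np.ndarray
    rotation: np.ndarray
    scale: float
    classes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        Q = self.rotation
        if not np.allclose(Q.T @ Q, np.eye(Q.shape[0]), atol=1e-8):
            raise ValueError("rotation matrix is not orthogonal")

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X) - self.target_mean) @ self.rotation * self.scale \
            + self.source_mean


def procrustes_align(
    source_means: np.ndarray, target_means: np.ndarray,
    classes: tuple[str, ...] = (),
) -> AlignmentTransform:
    """Least-squares full Procrustes fit of target class means onto source.

    Both mean sets must come from embeddings min-max normalized to [0, 1]
    per dimension; at least three classes are required in 4 dimensions.
    """
    S = np.asarray(source_means, dtype=float)
    T = np.asarray(target_means, dtype=float)
    if S.shape != T.shape:
        raise ValueError("source and target class means must share shape")
    if len(S) < 3:
        raise ValueError("Procrustes underdetermined with < 3 classes")
    mu_s, mu_t = S.mean(axis=0), T.mean(axis=0)
    S0, T0 = S - mu_s, T - mu_t
    U, sig, Vt = np.linalg.svd(T0.T @ S0)
    Q = U @ Vt
    denom = float(np.sum(T0**2))
    scale = float(sig.sum() / denom) if denom > 0 else 1.0
    return AlignmentTransform(
        source_mean=mu_s, target_mean=mu_t, rotation=Q, scale=scale,
        classes=tuple(classes),
    )


# ---------------------------------------------------------------------------
# cross-session / cross-subject decoding
# ---------------------------------------------------------------------------

def _session_points(embedding, track, dims):
    coords = minmax_normalize(embedding.coords[:, :dims])
    labels = labels_on_pop_grid(track)[embedding.kept_time_index]
    return coords, labels


def cross_session_decode(
    train: tuple,
    test: tuple,
    split: tuple[tuple[str, ...], tuple[str, ...]],
    seed: int = 0,
    aligned: bool = True,
    n_reps: int = 20,
    dims: int = ALIGN_DIMS,
    svm_gamma: float = 1.0,
) -> DecodingReport | None:
    """Train on one session's decoding-set samples, test on another's.

    ``train`` and ``test`` are ``(embedding, LabelTrack)`` pairs. The
    Procrustes transform is fitted on the alignment classes' mean vectors
    only; the SVM (RBF kernel, kernel scale 1, one-vs-one) is trained on
    class-balanced subsamples of the train session's decoding-set points
    and evaluated on all aligned test-session decoding-set points, averaged
    over ``n_reps`` Monte Carlo repetitions. ``aligned=False`` skips the
    transform (control). Returns ``None`` when a decoding class is absent.
    """
    align_set, decode_set = split
    tr_coords, tr_labels = _session_points(*train, dims)
    te_coords, te_labels = _session_points(*test, dims)

    for c in decode_set:
        if not np.any(tr_labels == c) or not np.any(te_labels == c):
            warnings.warn(f"decoding class {c!r} absent; split skipped",
                          stacklevel=2)
            return None
    try:
        src = np.stack([tr_coords[tr_labels == c].mean(axis=0)
                        for c in align_set])
        tgt = np.stack([te_coords[te_labels == c].mean(axis=0)
                        for c in align_set])
    except ValueError:
        warnings.warn("alignment class absent; split skipped", stacklevel=2)
        return None
    if aligned:
        transform = procrustes_align(src, tgt, classes=align_set)
        te_coords = transform.transform(te_coords)

    # audit: alignment used only alignment-class means; decoding-set sample
    # indices are disjoint from alignment-set indices by class disjointness
    assert not set(align_set) & set(decode_set)

    tr_idx = {c: np.nonzero(tr_labels == c)[0] for c in decode_set}
    n_bal = min(len(v) for v in tr_idx.values())
    te_mask = np.isin(te_labels, decode_set)
    Xte, yte = te_coords[te_mask], te_labels[te_mask]
    seed_seq = np.atleast_1d(np.asarray(seed)).astype(np.int64).tolist()
    rng = np.random.default_rng([*seed_seq, 13])
    accs = []
    recall_acc: dict[str, list] = {c: [] for c in decode_set}
    for _ in range(n_reps):
        pick = np.concatenate([
            rng.choice(tr_idx[c], size=n_bal, replace=False)
            for c in decode_set
        ])
        clf = SVC(kernel="rbf", gamma=svm_gamma, C=1.0,
                  decision_function_shape="ovo")
        clf.fit(tr_coords[pick], tr_labels[pick])
        y_pred = clf.predict(Xte)
        rep = _report(yte, y_pred, decode_set)
        accs.append(rep.mean_per_class_accuracy)
        for c, r in rep.per_class_recalls.items():
            recall_acc[c].append(r)
    return DecodingReport(
        mean_per_class_accuracy=float(np.mean(accs)),
        per_class_recalls={c: float(np.mean(v)) for c, v in recall_acc.items()},
        split_id="+".join(align_set) + "|" + "+".join(decode_set),
        n_runs=n_reps,
        extras={"aligned": aligned, "accuracy_std": float(np.std(accs)),
                "n_balanced": int(n_bal)},
    )


def generalization_matrix(
    sessions: list[tuple],
    splits: list[tuple] | None = None,
    seed: int = 0,
    aligned: bool = True,
    n_reps: int = 20,
    ids: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Accuracy matrix over all ordered session pairs (diagonal included).

    Each entry averages :func:`cross_session_decode` over the given splits
    (default: all 15 splits with four alignment classes). Returns the
    matrix plus two per-session generalization accuracies: the row mean
    over all sessions (diagonal included) and over off-diagonal entries.
    """
    splits = splits or class_splits(4)
    n = len(sessions)
    ids = ids or [str(i) for i in range(n)]
    M = np.full((n, n), np.nan)
    for i in range(n):
        for j in range(n):
            accs = []
            for s_idx, split in enumerate(splits):
                rep = cross_session_decode(
                    sessions[i], sessions[j], split,
                    seed=[seed, i, j, s_idx], aligned=aligned, n_reps=n_reps,
                )
                if rep is not None:
                    accs.append(rep.mean_per_class_accuracy)
            if accs:
                M[i, j] = float(np.mean(accs))
    df = pd.DataFrame(M, index=ids, columns=ids)
    gen_all = df.mean(axis=1)
    off = df.copy()
    np.fill_diagonal(off.values, np.nan)
    gen_off = off.mean(axis=1)
    return df, gen_all, gen_off


# ---------------------------------------------------------------------------
# ablations
# ---------------------------------------------------------------------------

def _remove_units_session(session: Session, drop: np.ndarray) -> Session:
    keep = np.setdiff1d(np.arange(session.n_units), drop)
    return Session(
        spike_times=[session.spike_times[i] for i in keep],
        units=session.units.iloc[keep].reset_index(drop=True),
        paw_velocity=session.paw_velocity,
        labels=session.labels,
        duration_s=session.duration_s,
        meta=dict(session.meta),
    )


def ablation_harness(
    sessions: list[Session],
    mode: str,
    params: dict | None = None,
    seed: int = 0,
    splits: list[tuple] | None = None,
    n_reps: int = 5,
    min_active: int = 15,
    enforce_floor: bool = False,
) -> pd.DataFrame:
    """Generalization accuracy after removing units or whole areas.

    ``remove_k_units`` drops k random units per session (k from
    ``params['k_list']``, embedding dimension 20 for k <= 40 and 10 above,
    matching the reduced unit counts); ``remove_area`` removes one area's
    units plus random padding so every condition removes
    ``max(#M2, #M1, #S1)`` units, embedding dimension 10. Conditions where
    a session would retain fewer units than the target dimensionality are
    skipped. Accuracies are averaged over all ordered session pairs.
    """
    from .manifold import lem_pipeline, preprocess_population

    params = params or {}
    splits = splits or class_splits(4)[:3]
    conditions: list[tuple[str, object]] = []
    if mode == "remove_k_units":
        conditions = [("k", k) for k in params.get("k_list", (0, 20, 40, 60, 80))]
    elif mode == "remove_area":
        conditions = [("area", a) for a in ("M2", "M1", "S1")]
    else:
        raise ValueError(f"unknown ablation mode: {mode}")

    rows = []
    for cond_idx, (cond_name, cond) in enumerate(conditions):
        if mode == "remove_k_units":
            dims = 20 if int(cond) <= 40 else 10
        else:
            dims = 10
        embedded = []
        for s_idx, sess in enumerate(sessions):
            rng = np.random.default_rng([seed, s_idx, cond_idx])
            if mode == "remove_k_units":
                k = int(cond)
                if sess.n_units - k <= dims:
                    embedded.append(None)
                    continue
                drop = rng.choice(sess.n_units, size=k, replace=False)
            else:
                areas = sess.units["area"].to_numpy()
                n_max = max(int(np.sum(areas == a)) for a in ("M2", "M1", "S1"))
                in_area = np.nonzero(areas == cond)[0]
                others = np.nonzero(areas != cond)[0]
                pad = rng.choice(
                    others, size=n_max - len(in_area), replace=False
                ) if n_max > len(in_area) else np.array([], dtype=int)
                drop = np.concatenate([in_area, pad])
                if sess.n_units - len(drop) <= dims:
                    embedded.append(None)
                    continue
            sub = _remove_units_session(sess, drop)
            bpm = preprocess_population(sub, min_active=min_active)
            emb = lem_pipeline(bpm, dims=dims, enforce_floor=enforce_floor)
            embedded.append((emb, LabelTrack(sub.labels)))
        pairs = [
            (i, j)
            for i in range(len(sessions))
            for j in range(len(sessions))
            if embedded[i] is not None and embedded[j] is not None
        ]
        accs = []
        for i, j in pairs:
            for s_idx, split in enumerate(splits):
                rep = cross_session_decode(
                    embedded[i], embedded[j], split,
                    seed=[seed, i, j, s_idx], n_reps=n_reps,
                )
                if rep is not None:
                    accs.append(rep.mean_per_class_accuracy)
        rows.append(
            {
                "mode": mode,
                cond_name: cond,
                "dims": dims,
                "accuracy": float(np.mean(accs)) if accs else np.nan,
                "n_runs": len(accs),
            }
        )
    return pd.DataFrame(rows)
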