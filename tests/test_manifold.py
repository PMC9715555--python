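"""Population preprocessing, graphs, spectral embedding and controls."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

import pawcode as pc
from pawcode.manifold import (
    BinaryPopulationMatrix,
    NeighborGraph,
    _knn_indices,
    control_transforms,
    estimate_dimensionality,
    isomap_embed,
    lem_pipeline,
    mutual_knn_graph,
    pca_embed,
    preprocess_population,
    spectral_embed,
)
from pawcode.session import Session, make_units_table


def _mini_session(spike_times, duration=0.2):
    n = len(spike_times)
    units = make_units_table(
        [{"unit_id": i, "area": "M1", "hemisphere": "L",
          "region": "forelimb"} for i in range(n)]
    )
    return Session(
        spike_times=[np.asarray(s, dtype=float) for s in spike_times],
        units=units,
        paw_velocity=np.zeros((int(duration * 100), 4)),
        labels=np.array(["rest"] * int(duration * 2)),
        duration_s=duration,
    )


class TestPreprocess:
    def test_binarize_and_keep_all_columns(self):
        sess = _mini_session([[0.15, 0.16], [0.05]])
        bpm = preprocess_population(sess, min_active=1, min_time_points=0)
        assert bpm.matrix.tolist() == [[0, 1], [1, 0]]
        assert bpm.kept_time_index.tolist() == [0, 1]

    def test_unreachable_min_active_flags_session(self):
        sess = _mini_session([[0.15], [0.05]])
        bpm = preprocess_population(sess, min_active=3)
        assert bpm.matrix.shape[1] == 0
        assert bpm.flagged

    def test_full_session_filter(self, session_a):
        bpm = preprocess_population(session_a)
        assert bpm.n_total_bins == 6000
        assert bpm.matrix.shape[1] <= 6000
        assert np.all(bpm.matrix.sum(axis=0) >= 15)


class TestMutualKnn:
    def test_equidistant_triangle_is_complete(self):
        X = np.eye(3)
        g = mutual_knn_graph(X, k_fraction=0.67, metric="hamming")
        assert g.k == 2
        assert g.W.toarray().sum() == 6  # all off-diagonal edges

    def test_separated_clusters_stay_disconnected(self):
        rng = np.random.default_rng(0)
        a = (rng.random((20, 40)) < 0.1).astype(np.uint8)
        b = 1 - (rng.random((20, 40)) < 0.1).astype(np.uint8)
        X = np.vstack([a, b])
        g = mutual_knn_graph(X, k_fraction=0.1, metric="hamming")
        n_comp, labels = connected_components(g.W, directed=False)
        assert n_comp >= 2
        assert len(set(labels[:20]) & set(labels[20:])) == 0

    def test_mutual_graph_within_directed_graph(self):
        rng = np.random.default_rng(1)
        X = (rng.random((60, 30)) < 0.4).astype(np.uint8)
        k = 5
        nbrs = _knn_indices(X, k, "hamming")
        g = mutual_knn_graph(X, k_fraction=k / 60, metric="hamming")
        directed = set()
        for i, row in enumerate(nbrs):
            directed |= {(i, j) for j in row}
        W = g.W.tocoo()
        for i, j in zip(W.row, W.col):
            assert (i, j) in directed and (j, i) in directed

    def test_distance_ties_break_by_ascending_index(self):
        # four identical points: neighbors must be the lowest-index others
        X = np.zeros((4, 8), dtype=np.uint8)
        nbrs = _knn_indices(X, 2, "hamming")
        assert nbrs[0].tolist() == [1, 2]
        assert nbrs[3].tolist() == [0, 1]

    def test_k_too_large_rejected(self):
        with pytest.raises(ValueError, match="k="):
            _knn_indices(np.zeros((3, 4)), 3, "hamming")


class TestSpectralEmbed:
    @staticmethod
    def _graph_from_adjacency(W):
        return NeighborGraph(W=sp.csr_matrix(W.astype(float)), k=1,
                             metric="euclidean")

    def test_path_graph_fiedler_vector_is_monotone(self):
        W = np.zeros((4, 4))
        for i in range(3):
            W[i, i + 1] = W[i + 1, i] = 1
        emb = spectral_embed(self._graph_from_adjacency(W), d=2)
        fiedler = emb.coords[:, 0]
        diffs = np.diff(fiedler)
        assert np.all(diffs > 0) or np.all(diffs < 0)

    def test_disconnected_cliques_restrict_to_larger(self):
        W = np.zeros((7, 7))
        W[:3, :3] = 1 - np.eye(3)
        W[3:, 3:] = 1 - np.eye(4)
        with pytest.warns(UserWarning, match="components"):
            emb = spectral_embed(self._graph_from_adjacency(W), d=2)
        assert emb.coords.shape[0] == 4
        assert emb.kept_time_index.tolist() == [3, 4, 5, 6]

    def test_eigenvalues_nonnegative_and_ascending(self):
        rng = np.random.default_rng(2)
        X = (rng.random((120, 30)) < 0.4).astype(np.uint8)
        g = mutual_knn_graph(X, k_fraction=0.1, metric="hamming")
        emb = spectral_embed(g, d=6)
        assert np.all(emb.eigenvalues >= 0)
        assert np.all(np.diff(emb.eigenvalues) >= -1e-12)

    def test_sign_convention_largest_entry_positive(self):
        rng = np.random.default_rng(3)
        X = (rng.random((100, 25)) < 0.4).astype(np.uint8)
        g = mutual_knn_graph(X, k_fraction=0.08, metric="hamming")
        emb = spectral_embed(g, d=4)
        for d in range(emb.coords.shape[1]):
            v = emb.coords[:, d]
            assert v[np.argmax(np.abs(v))] > 0


class TestLemPipeline:
    def test_floor_enforced_for_full_analyses(self, tiny_session):
        bpm = preprocess_population(tiny_session, min_active=2)
        with pytest.raises(ValueError, match="5000"):
            lem_pipeline(bpm)

    def test_bit_identical_on_rerun(self, small_session):
        bpm = preprocess_population(small_session)
        e1 = lem_pipeline(bpm, enforce_floor=False)
        e2 = lem_pipeline(bpm, enforce_floor=False)
        assert np.array_equal(e1.coords, e2.coords)

    def test_invariant_to_unit_reordering(self, small_session):
        bpm = preprocess_population(small_session)
        e1 = lem_pipeline(bpm, enforce_floor=False)
        perm = np.random.default_rng(4).permutation(bpm.matrix.shape[0])
        bpm2 = BinaryPopulationMatrix(
            matrix=bpm.matrix[perm],
            kept_time_index=bpm.kept_time_index,
            min_active=bpm.min_active,
            n_total_bins=bpm.n_total_bins,
        )
        e2 = lem_pipeline(bpm2, enforce_floor=False)
        np.testing.assert_allclose(e1.coords, e2.coords, atol=1e-9)

    def test_kept_index_threaded_through(self, emb_a, session_a):
        bpm = preprocess_population(session_a)
        assert np.all(np.isin(emb_a.kept_time_index, bpm.kept_time_index))
        assert emb_a.coords.shape == (len(emb_a.kept_time_index), 20)


class TestControls:
    @pytest.fixture()
    def bpm(self):
        rng = np.random.default_rng(5)
        m = (rng.random((10, 300)) < 0.4).astype(np.uint8)
        return BinaryPopulationMatrix(
            matrix=m, kept_time_index=np.arange(300), min_active=1,
            n_total_bins=300,
        )

    def test_time_shuffle_preserves_rows_and_column_multiset(self, bpm):
        out = control_transforms(bpm, "time_shuffle", seed=1)
        assert np.array_equal(out.matrix.sum(1), bpm.matrix.sum(1))
        orig_cols = sorted(map(tuple, bpm.matrix.T.tolist()))
        new_cols = sorted(map(tuple, out.matrix.T.tolist()))
        assert orig_cols == new_cols

    def test_neuron_shuffle_preserves_row_sums_only(self, bpm):
        out = control_transforms(bpm, "neuron_shuffle", seed=1)
        assert np.array_equal(out.matrix.sum(1), bpm.matrix.sum(1))
        assert not np.array_equal(out.matrix, bpm.matrix)

    def test_time_shift_rows_are_rotations(self, bpm):
        out = control_transforms(bpm, "time_shift", seed=1)
        for i in range(bpm.matrix.shape[0]):
            row, orig = out.matrix[i], bpm.matrix[i]
            assert any(
                np.array_equal(np.roll(orig, s), row)
                for s in range(len(orig))
            )

    def test_unknown_mode_rejected(self, bpm):
        with pytest.raises(ValueError, match="mode"):
            control_transforms(bpm, "flip", seed=0)


class TestDimensionality:
    def test_scale_invariance(self):
        rng = np.random.default_rng(6)
        X = rng.random((800, 3))
        assert estimate_dimensionality(X) == pytest.approx(
            estimate_dimensionality(10 * X)
        )

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="500"):
            estimate_dimensionality(np.random.default_rng(0).random((100, 3)))


class TestAlternativeEmbeddings:
    def test_pca_rank_one_counts(self):
        # unit counts [1, 2] and [2, 4]: rank-1 variation across time
        sess = _mini_session(
            [[0.01, 0.11, 0.12], [0.02, 0.03, 0.11, 0.12, 0.13, 0.14]],
            duration=0.2,
        )
        emb = pca_embed(sess, d=2, min_active=1)
        assert emb.method == "PCA"
        assert emb.eigenvalues[0] > 0
        assert emb.eigenvalues[1] <= 1e-12

    def test_pca_matches_dense_covariance_oracle(self, tiny_session):
        emb = pca_embed(tiny_session, d=3, min_active=2)
        counts = tiny_session.spike_counts(0.1).astype(float)
        keep = (counts >= 1).sum(axis=0) >= 2
        X = counts[:, keep].T
        Xc = X - X.mean(axis=0)
        vals, vecs = np.linalg.eigh(np.cov(Xc.T))
        order = np.argsort(vals)[::-1][:3]
        np.testing.assert_allclose(
            np.abs(emb.coords.T @ emb.coords),
            np.abs((Xc @ vecs[:, order]).T @ (Xc @ vecs[:, order])),
            rtol=1e-6, atol=1e-6,
        )

    def test_pca_variance_bounded_by_total(self, tiny_session):
        emb = pca_embed(tiny_session, d=5, min_active=2)
        counts = tiny_session.spike_counts(0.1).astype(float)
        keep = (counts >= 1).sum(axis=0) >= 2
        total_var = counts[:, keep].T.var(axis=0, ddof=1).sum()
        assert emb.eigenvalues.sum() <= total_var + 1e-9

    def test_landmark_isomap_with_all_landmarks_matches_classical(self):
        rng = np.random.default_rng(7)
        m = (rng.random((25, 150)) < 0.35).astype(np.uint8)
        bpm = BinaryPopulationMatrix(
            matrix=m, kept_time_index=np.arange(150), min_active=1,
            n_total_bins=150,
        )
        emb = isomap_embed(bpm, d=3, k_fraction=0.08,
                           landmark_fraction=1.0, seed=0)
        # classical MDS oracle on the full geodesic matrix
        from scipy.sparse.csgraph import dijkstra

        g = mutual_knn_graph(m.T, 0.08, metric="hamming",
                             keep_distances=True)
        comp = np.arange(150)
        geo = dijkstra(g.distances, directed=False)
        keep = ~np.isinf(geo).any(axis=0)
        geo = geo[np.ix_(keep, keep)]
        n = geo.shape[0]
        J = np.eye(n) - 1 / n
        B = -0.5 * J @ (geo**2) @ J
        vals, vecs = np.linalg.eigh(B)
        order = np.argsort(vals)[::-1][:3]
        oracle = vecs[:, order] * np.sqrt(np.maximum(vals[order], 0))
        from scipy.spatial.distance import pdist

        np.testing.assert_allclose(
            pdist(emb.coords), pdist(oracle), atol=1e-6
        )

    def test_isomap_deterministic_under_seed(self):
        rng = np.random.default_rng(8)
        m = (rng.random((20, 120)) < 0.4).astype(np.uint8)
        bpm = BinaryPopulationMatrix(
            matrix=m, kept_time_index=np.arange(120), min_active=1,
            n_total_bins=120,
        )
        e1 = isomap_embed(bpm, d=3, k_fraction=0.1, seed=5)
        e2 = isomap_embed(bpm, d=3, k_fraction=0.1, seed=5)
        np.testing.assert_array_equal(e1.coords, e2.coords)


class TestAreaSubset:
    def test_exact_twenty_units_uses_all(self, shared_arch):
        plan = {("M1", "L", "forelimb"): 10, ("M1", "L", "hindlimb"): 10,
                ("S1", "R", "forelimb"): 4}
        cfg = pc.SessionConfig(
            n_units=24, units_metadata_plan=plan, duration_s=300.0, seed=13
        )
        sess = pc.generate_session(shared_arch, cfg)
        emb = pc.area_subset_embedding(sess, "M1", n_units=20, d=6, seed=0,
                                       min_active=5)
        assert emb is not None
        assert sorted(emb.params["sampled_units"]) == list(range(20))
        assert emb.coords.shape[1] == 5  # five usable dimensions

    def test_insufficient_units_skipped(self, tiny_session):
        with pytest.warns(UserWarning, match="skipped"):
            out = pc.area_subset_embedding(tiny_session, "S1", n_units=20)
        assert out is None
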