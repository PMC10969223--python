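import numpy as np
import pytest
import scipy.sparse as sp
from sklearn.metrics import balanced_accuracy_score

from sctme import tumor as T
from sctme.cnv import CNVMatrix, estimate_cnv, select_reference
from sctme.config import PipelineConfig

import pandas as pd


def as_cnv(values):
    values = np.asarray(values, dtype=float)
    wm = pd.DataFrame({
        "chromosome": ["chr1"] * values.shape[1],
        "gene_start": np.arange(values.shape[1]) * 10,
        "gene_end": np.arange(values.shape[1]) * 10 + 10,
    })
    return CNVMatrix(values=values, window_map=wm,
                     cell_ids=pd.Index([f"c{i}" for i in range(len(values))]))


class TestReduceCnv:
    def test_rank_deficient_plane(self):
        rng = np.random.default_rng(0)
        basis = rng.normal(size=(2, 20))
        data = rng.normal(size=(200, 2)) @ basis
        emb = T.reduce_cnv(as_cnv(data), n_components=15, seed=0)
        var = emb.var(axis=0)
        assert var[2:].max() < 1e-20 * var[0]

    def test_duplicate_cells_identical_embedding(self):
        rng = np.random.default_rng(1)
        data = rng.normal(size=(50, 20))
        data[7] = data[3]
        emb = T.reduce_cnv(as_cnv(data), n_components=5, seed=0)
        assert np.allclose(emb[7], emb[3])

    def test_deterministic_and_sign_fixed(self):
        rng = np.random.default_rng(2)
        data = rng.normal(size=(60, 20))
        a = T.reduce_cnv(as_cnv(data), n_components=5, seed=0)
        b = T.reduce_cnv(as_cnv(data), n_components=5, seed=0)
        assert np.array_equal(a, b)

    def test_fewer_windows_than_components_warns(self):
        rng = np.random.default_rng(3)
        data = rng.normal(size=(50, 8))
        with pytest.warns(UserWarning, match="reducing components"):
            emb = T.reduce_cnv(as_cnv(data), n_components=15, seed=0)
        assert emb.shape == (50, 8)

    def test_too_few_cells_rejected(self):
        with pytest.raises(ValueError, match="components"):
            T.reduce_cnv(as_cnv(np.zeros((5, 20))), n_components=15, seed=0)


class TestKnnGraph:
    def test_collinear_middle_degree(self):
        pts = np.array([[0.0], [1.0], [2.0]])
        adj = T.build_knn_graph(pts, k=1)
        deg = np.asarray(adj.sum(axis=1)).ravel()
        assert deg[1] == 2

    def test_symmetric(self):
        rng = np.random.default_rng(4)
        adj = T.build_knn_graph(rng.normal(size=(80, 3)), k=5)
        assert (adj != adj.T).nnz == 0

    def test_separated_blobs_no_cross_edges(self):
        """Brute-force distance oracle: with two blobs 10 apart (σ=0.1),
        every kNN edge must join points of the same blob."""
        rng = np.random.default_rng(5)
        a = rng.normal(0, 0.1, size=(100, 2))
        b = rng.normal(10, 0.1, size=(100, 2))
        pts = np.vstack([a, b])
        adj = T.build_knn_graph(pts, k=5).tocoo()
        blob = np.array([0] * 100 + [1] * 100)
        assert np.all(blob[adj.row] == blob[adj.col])
        # oracle: nearest neighbors by explicit pairwise distances agree
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        np.fill_diagonal(d, np.inf)
        dense = adj.toarray()
        for i in range(0, 200, 25):
            nn = set(np.argsort(d[i], kind="stable")[:5])
            assert nn <= set(np.flatnonzero(dense[i]))

    def test_k_too_large_rejected(self):
        with pytest.raises(ValueError, match="k="):
            T.build_knn_graph(np.zeros((5, 2)), k=5)


def clique_graph(sizes, bridges=()):
    n = sum(sizes)
    A = np.zeros((n, n))
    start = 0
    for s in sizes:
        A[start:start + s, start:start + s] = 1
        start += s
    np.fill_diagonal(A, 0)
    for i, j in bridges:
        A[i, j] = A[j, i] = 1
    return sp.csr_matrix(A)


class TestLouvain:
    def test_disconnected_cliques_recovered(self):
        g = clique_graph([6, 6])
        part = T.louvain_cluster(g, resolution=2.0, seed=0)
        assert part.n_clusters == 2
        assert len(set(part.labels[:6])) == 1
        assert len(set(part.labels[6:])) == 1

    def test_edgeless_graph_singletons(self):
        g = sp.csr_matrix((7, 7))
        part = T.louvain_cluster(g, resolution=2.0, seed=0)
        assert part.n_clusters == 7

    def test_bridged_cliques_split(self):
        g = clique_graph([6, 6], bridges=[(0, 6)])
        part = T.louvain_cluster(g, resolution=2.0, seed=0)
        assert part.n_clusters == 2
        assert len(set(part.labels[:6])) == 1

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            T.louvain_cluster(sp.csr_matrix((0, 0)), seed=0)

    def test_deterministic(self):
        rng = np.random.default_rng(6)
        pts = rng.normal(size=(150, 3))
        g = T.build_knn_graph(pts, k=8)
        a = T.louvain_cluster(g, resolution=2.0, seed=3)
        b = T.louvain_cluster(g, resolution=2.0, seed=3)
        assert np.array_equal(a.labels, b.labels)


class TestAggregateAdjacency:
    def test_no_cross_edges_zero(self):
        g = clique_graph([3, 4])
        part = T.ClusterPartition(np.array([0] * 3 + [1] * 4), 2)
        conn = T.aggregate_adjacency(g, part)
        assert conn[0, 1] == 0

    def test_size_normalization(self):
        g = clique_graph([2, 3], bridges=[(0, 2), (0, 3), (1, 4)])
        part = T.ClusterPartition(np.array([0, 0, 1, 1, 1]), 2)
        conn = T.aggregate_adjacency(g, part)
        assert conn[0, 1] == pytest.approx(3 / 6)
        raw = T.aggregate_adjacency(g, part, normalized=False)
        assert raw[0, 1] == pytest.approx(3)

    def test_symmetric_zero_diagonal(self):
        rng = np.random.default_rng(7)
        g = T.build_knn_graph(rng.normal(size=(60, 2)), k=4)
        part = T.louvain_cluster(g, seed=0)
        conn = T.aggregate_adjacency(g, part)
        assert np.allclose(conn, conn.T)
        assert np.all(np.diag(conn) == 0)


class TestSeedSelection:
    def make_part(self, sizes):
        labels = np.repeat(np.arange(len(sizes)), sizes)
        return T.ClusterPartition(labels, len(sizes))

    def test_strictly_greater_than_fraction(self):
        part = self.make_part([100, 100])
        ref = np.zeros(200, dtype=bool)
        ref[:21] = True        # cluster 0: 21% reference
        ref[100:120] = True    # cluster 1: exactly 20%
        state = T.select_seed_clusters(part, ref, fraction=0.20)
        assert state.seed_set == {0}
        assert state.unprocessed == {1}

    def test_all_reference_all_seeds(self):
        part = self.make_part([10, 10])
        state = T.select_seed_clusters(part, np.ones(20, dtype=bool))
        assert state.seed_set == {0, 1} and not state.unprocessed

    def test_no_seeds_errors(self):
        part = self.make_part([10])
        with pytest.raises(ValueError, match="seed"):
            T.select_seed_clusters(part, np.zeros(10, dtype=bool))


def grow_oracle(conn, seed_set, unprocessed, mode="max"):
    """Independent brute-force re-implementation of the growth loop."""
    seeds, unp = set(seed_set), set(unprocessed)
    while unp:
        members = sorted(seeds)
        if len(members) < 2:
            tau = 0.0
        else:
            tau = min(
                (max if mode == "max" else sum)(
                    conn[s][t] for t in members if t != s)
                for s in members)
        scored = []
        for c in sorted(unp):
            scored.append((
                (max if mode == "max" else sum)(conn[c][s] for s in members),
                -c))
        best_score, neg_c = max(scored)
        if best_score >= tau:
            seeds.add(-neg_c)
            unp.discard(-neg_c)
        else:
            break
    return seeds


class TestGrowNormalSet:
    def test_zero_connectivity_never_absorbed(self):
        conn = np.array([[0, 0.5, 0], [0.5, 0, 0], [0, 0, 0]], dtype=float)
        state = T.SeedState(seed_set={0, 1}, unprocessed={2})
        assert T.grow_normal_set(conn, state) == {0, 1}

    def test_single_candidate_above_tau_absorbed(self):
        conn = np.array([[0, 0.2, 0.9], [0.2, 0, 0.1], [0.9, 0.1, 0]])
        state = T.SeedState(seed_set={0, 1}, unprocessed={2})
        assert T.grow_normal_set(conn, state) == {0, 1, 2}

    def test_single_seed_tau_zero(self):
        conn = np.array([[0, 0.01], [0.01, 0]])
        state = T.SeedState(seed_set={0}, unprocessed={1})
        assert T.grow_normal_set(conn, state) == {0, 1}

    @pytest.mark.parametrize("mode", ["max", "sum"])
    def test_matches_brute_force_oracle(self, mode):
        rng = np.random.default_rng(42)
        for _ in range(200):
            k = rng.integers(2, 9)
            conn = rng.random((k, k)) * (rng.random((k, k)) < 0.6)
            conn = (conn + conn.T) / 2
            np.fill_diagonal(conn, 0)
            n_seed = rng.integers(1, k)
            seeds = set(rng.choice(k, size=n_seed, replace=False).tolist())
            unp = set(range(k)) - seeds
            got = T.grow_normal_set(conn, T.SeedState(set(seeds), set(unp)),
                                    mode=mode)
            want = grow_oracle(conn.tolist(), seeds, unp, mode=mode)
            assert got == want


class TestInitialDecision:
    def test_labels_constant_within_cluster(self):
        part = T.ClusterPartition(np.array([0, 1, 0, 2, 1]), 3)
        init = T.initial_decision(part, {0, 2})
        assert list(init) == [True, False, True, True, False]

    def test_all_normal(self):
        part = T.ClusterPartition(np.array([0, 1]), 2)
        assert T.initial_decision(part, {0, 1}).all()


class TestNormalGmm:
    def test_bic_selects_single_component(self):
        """Data from one Gaussian: BIC should pick 1 component in ≥ 90% of
        20 replicates."""
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(500, 4))
            model = T.fit_normal_gmm(X, np.ones(500, dtype=bool), seed=seed)
            hits += model.n_components == 1
        assert hits >= 18

    def test_density_decreases_away_from_mean(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(300, 3))
        model = T.fit_normal_gmm(X, np.ones(300, dtype=bool), seed=0)
        center = model.means_[0:1]
        far = center + 10 * np.sqrt(model.covariances_[0:1])
        assert model.score_samples(center) >= model.score_samples(far)

    def test_refit_identical(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(200, 3))
        a = T.fit_normal_gmm(X, np.ones(200, dtype=bool), seed=5)
        b = T.fit_normal_gmm(X, np.ones(200, dtype=bool), seed=5)
        assert np.array_equal(a.means_, b.means_)
        assert np.array_equal(a.covariances_, b.covariances_)

    def test_too_few_cells_rejected(self):
        X = np.zeros((100, 3))
        mask = np.zeros(100, dtype=bool)
        mask[:49] = True
        with pytest.raises(ValueError, match="50"):
            T.fit_normal_gmm(X, mask, seed=0)


class TestWeightedScore:
    def test_best_explained_cell_zero(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(200, 3))
        model = T.fit_normal_gmm(X, np.ones(200, dtype=bool), seed=0)
        w = T.weighted_cnv_score(model, X, np.ones(200))
        assert w.min() == 0.0

    def test_zero_cnv_score_zero_product(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(100, 3))
        model = T.fit_normal_gmm(X, np.ones(100, dtype=bool), seed=0)
        w = T.weighted_cnv_score(model, X, np.zeros(100))
        assert np.all(w == 0.0)


class TestBimodalCall:
    def test_well_separated_mixture(self):
        """Half N(0, 0.1²), half N(5, 0.1²): misclassification < 1%."""
        rng = np.random.default_rng(0)
        lo = rng.normal(0, 0.1, 500)
        hi = rng.normal(5, 0.1, 500)
        scores = np.concatenate([lo, hi])
        call, thr = T.bimodal_call(scores, seed=0)
        truth = np.array([False] * 500 + [True] * 500)
        assert (call != truth).mean() < 0.01
        assert thr is not None

    def test_constant_scores_guard(self):
        with pytest.warns(UserWarning, match="constant|unimodal"):
            call, thr = T.bimodal_call(np.full(100, 2.0), seed=0)
        assert not call.any() and thr is None

    def test_threshold_between_component_means(self):
        rng = np.random.default_rng(1)
        scores = np.concatenate([rng.normal(0.5, 0.05, 400),
                                 rng.normal(6, 0.3, 400)])
        call, thr = T.bimodal_call(scores, seed=0)
        assert 0.5 < thr < 6

    def test_otsu_alternative(self):
        rng = np.random.default_rng(2)
        scores = np.concatenate([rng.normal(0, 0.1, 300),
                                 rng.normal(5, 0.1, 300)])
        call, thr = T.bimodal_call(scores, seed=0, method="otsu")
        truth = np.array([False] * 300 + [True] * 300)
        assert (call != truth).mean() < 0.01


class TestEndToEnd:
    def test_tiny_cohort_calls(self, tiny_cohort):
        ds, truth = tiny_cohort
        cnv = estimate_cnv(ds, select_reference(ds.cells))
        calls = T.call_tumors(ds, cnv, PipelineConfig(), seed=11)
        lab = truth.tumor_labels.to_numpy()
        assert balanced_accuracy_score(lab, calls["is_tumor"].to_numpy()) > 0.9
        # tumor calls are reported only on epithelial cells
        epi = (ds.cells["major_type"] == "Epithelial").to_numpy()
        assert not (calls["is_tumor"].to_numpy() & ~epi).any()
        assert (calls["weighted_score"]
                == calls["gmm_weight"] * calls["cnv_score"]).all()
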