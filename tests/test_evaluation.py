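import numpy as np
import pytest

from sigrn import (
    AdjacencyMatrix,
    GroundTruthNetwork,
    ari,
    binarize,
    cluster_cells,
    confusion,
    early_precision_ratio,
    embed_cells,
    generate_cells,
    generation_auc,
    nmi,
    rank_edges,
    roc_auc,
    spearman_tf_target,
)
from sigrn.evaluation import Partition
from sigrn.io_formats import ExpressionMatrix
from sigrn.sem_vae_model import encode, init_params, sem_encode_transform


def _ranking_from_scores(scores):
    """Build an EdgeRanking over a 1-regulator universe from named scores."""
    from sigrn.grn_extraction import EdgeRanking

    items = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
    records = [(("r", t)[0], t, s) for t, s in items]
    return EdgeRanking(
        records=[("r", t, s) for t, s in items],
        candidate_universe={("r", t) for t in scores},
    )


def _truth(edges, universe):
    return GroundTruthNetwork(edges=set(edges), gene_universe=set(universe))


class TestBinarizeAndConfusion:
    def test_threshold_extremes(self):
        W = np.array([[0.0, 0.4], [0.9, 0.0]])
        A = AdjacencyMatrix(W, ["a", "b"])
        assert binarize(A, 0.0).sum() == 1  # only the max survives scaling > 0
        assert binarize(A, 1.0).sum() == 0

    def test_matches_elementwise_loop(self, rng):
        W = rng.standard_normal((5, 5))
        np.fill_diagonal(W, 0.0)
        A = AdjacencyMatrix(W, [f"g{i}" for i in range(5)])
        t = 0.5
        got = binarize(A, t)
        mags = np.abs(W)
        off = ~np.eye(5, dtype=bool)
        lo, hi = mags[off].min(), mags[off].max()
        for i in range(5):
            for j in range(5):
                if i == j:
                    assert got[i, j] == 0
                else:
                    scaled = (mags[i, j] - lo) / (hi - lo)
                    assert got[i, j] == int(scaled > t)

    def test_confusion_hadamard_counting(self, rng):
        Ap = (rng.random((5, 5)) > 0.5).astype(int)
        At = (rng.random((5, 5)) > 0.5).astype(int)
        np.fill_diagonal(Ap, 0)
        np.fill_diagonal(At, 0)
        c = confusion(Ap, At)
        tp = fp = fn = tn = 0
        for i in range(5):
            for j in range(5):
                if i == j:
                    continue
                tp += Ap[i, j] * At[i, j]
                fp += Ap[i, j] * (1 - At[i, j])
                fn += (1 - Ap[i, j]) * At[i, j]
                tn += (1 - Ap[i, j]) * (1 - At[i, j])
        assert (c.tp, c.fp, c.fn, c.tn) == (tp, fp, fn, tn)

    def test_perfect_and_inverted_prediction(self):
        At = np.array([[0, 1], [0, 0]])
        same = confusion(At, At)
        assert same.fp == 0 and same.fn == 0
        inv = confusion(1 - At - np.eye(2, dtype=int), At)
        assert inv.tp == 0


class TestRocAuc:
    def test_perfect_ranking(self):
        r = _ranking_from_scores({"a": 0.9, "b": 0.8, "c": 0.1, "d": 0.05})
        truth = _truth({("r", "a"), ("r", "b")}, {"r", "a", "b", "c", "d"})
        assert roc_auc(r, truth) == 1.0

    def test_all_tied_gives_half(self):
        r = _ranking_from_scores({"a": 0.5, "b": 0.5, "c": 0.5})
        truth = _truth({("r", "a")}, {"r", "a", "b", "c"})
        assert roc_auc(r, truth) == 0.5

    def test_reversal_identity(self, rng):
        from sigrn.grn_extraction import EdgeRanking

        scores = {f"t{i}": float(rng.integers(0, 5)) for i in range(12)}
        r = _ranking_from_scores(scores)
        truth = _truth({("r", "t0"), ("r", "t3"), ("r", "t7")}, {"r", *scores})
        rev_items = sorted(scores.items(), key=lambda kv: (kv[1], kv[0]))
        rev = EdgeRanking(
            records=[("r", t, -s) for t, s in rev_items],
            candidate_universe=r.candidate_universe,
        )
        assert roc_auc(r, truth) + roc_auc(rev, truth) == pytest.approx(1.0, abs=1e-12)

    def test_degenerate_truth_rejected(self):
        r = _ranking_from_scores({"a": 1.0, "b": 0.5})
        with pytest.raises(ValueError, match="positive"):
            roc_auc(r, _truth({("x", "y")}, {"x", "y"}))


class TestEarlyPrecisionRatio:
    def test_perfect_ranking_hits_inverse_density(self):
        scores = {f"t{i}": 1.0 - 0.01 * i for i in range(20)}
        r = _ranking_from_scores(scores)
        truth = _truth({("r", f"t{i}") for i in range(4)}, {"r", *scores})
        assert early_precision_ratio(r, truth) == pytest.approx(5.0)

    def test_half_right_fixture(self):
        # 12 candidates, 4 true, top-4 contains 2 true -> EPR = (2/4)/(4/12)
        scores = {f"t{i}": 12 - i for i in range(12)}
        r = _ranking_from_scores(scores)
        truth = _truth({("r", "t0"), ("r", "t1"), ("r", "t8"), ("r", "t9")},
                       {"r", *scores})
        assert early_precision_ratio(r, truth) == pytest.approx(1.5)


class TestPartitionMetrics:
    def test_identical_partitions(self):
        p = Partition(labels=[0, 0, 1, 1, 2])
        assert ari(p, p) == pytest.approx(1.0)
        assert nmi(p, p) == pytest.approx(1.0)

    def test_label_permutation_invariance(self):
        p1 = [0, 0, 1, 1, 2, 2]
        p2 = [1, 1, 2, 2, 0, 0]
        assert ari(p1, p2) == pytest.approx(1.0)
        assert nmi(p1, p2) == pytest.approx(1.0)

    def test_single_cluster_nmi_zero(self):
        assert nmi([0, 0, 1, 1], [5, 5, 5, 5]) == 0.0

    def test_symmetry(self, rng):
        p1 = list(rng.integers(0, 3, 20))
        p2 = list(rng.integers(0, 4, 20))
        assert ari(p1, p2) == pytest.approx(ari(p2, p1))
        assert nmi(p1, p2) == pytest.approx(nmi(p2, p1))


class TestEmbedAndCluster:
    def test_embedding_is_mu_composition(self, rng):
        params = init_params(["a", "b", "c"], rng)
        X = ExpressionMatrix(rng.standard_normal((6, 3)), list("uvwxyz"), ["a", "b", "c"])
        emb = embed_cells(X, params)
        n_mu, _ = encode(X.values, params)
        np.testing.assert_array_equal(emb, sem_encode_transform(n_mu, params.adjacency))

    def test_permuting_cells_permutes_rows(self, rng):
        params = init_params(["a", "b", "c"], rng)
        vals = rng.standard_normal((6, 3))
        X = ExpressionMatrix(vals, list("uvwxyz"), ["a", "b", "c"])
        perm = [3, 1, 0, 5, 4, 2]
        Xp = ExpressionMatrix(vals[perm], [X.cell_ids[i] for i in perm], ["a", "b", "c"])
        np.testing.assert_array_equal(embed_cells(Xp, params), embed_cells(X, params)[perm])

    def test_two_blobs_recovered(self, rng):
        blob1 = rng.standard_normal((60, 10)) + 12.0
        blob2 = rng.standard_normal((60, 10)) - 12.0
        emb = np.vstack([blob1, blob2])
        labels = [0] * 60 + [1] * 60
        part = cluster_cells(emb, n_clusters=2, seed=0)
        assert ari(part, Partition(labels=labels)) == pytest.approx(1.0)

    def test_clustering_deterministic_under_seed(self, rng):
        emb = rng.standard_normal((80, 6))
        a = cluster_cells(emb, n_clusters=3, seed=7)
        b = cluster_cells(emb, n_clusters=3, seed=7)
        assert a.labels == b.labels


class TestGeneration:
    def test_generated_shape(self, rng):
        params = init_params([f"g{i}" for i in range(5)], rng)
        cells = generate_cells(params, 17, rng)
        assert cells.shape == (17, 5)

    def test_same_distribution_indistinguishable(self, rng):
        # an i.i.d. draw from the same law: out-of-fold AUC ~ 0.5.  (A literal
        # copy is pathological: each test point's exact twin carries the
        # opposite label, so the forest anti-predicts instead of guessing.)
        real = rng.standard_normal((300, 8))
        fake = rng.standard_normal((300, 8))
        auc = generation_auc(real, fake, rng=0)
        assert abs(auc - 0.5) < 0.05

    def test_shift_separable(self, rng):
        real = rng.standard_normal((120, 8))
        auc = generation_auc(real, real + 25.0, rng=0)
        assert auc >= 0.99

    def test_fold_assignment_reproducible(self, rng):
        real = rng.standard_normal((60, 5))
        fake = rng.standard_normal((60, 5)) * 1.5
        assert generation_auc(real, fake, rng=3) == generation_auc(real, fake, rng=3)


class TestSpearman:
    def test_monotone_transform_gives_one(self, rng):
        tf = rng.random(50)
        vals = np.column_stack([tf, np.exp(tf)])
        X = ExpressionMatrix(vals, [f"c{i}" for i in range(50)], ["TF", "TGT"])
        table = spearman_tf_target(X, [("TF", "TGT")])
        assert table.loc[0, "rho"] == pytest.approx(1.0)

    def test_independent_columns_near_zero(self):
        rng = np.random.default_rng(11)
        vals = rng.standard_normal((1000, 2))
        X = ExpressionMatrix(vals, [f"c{i}" for i in range(1000)], ["a", "b"])
        table = spearman_tf_target(X, [("a", "b")])
        assert abs(table.loc[0, "rho"]) < 0.1

    def test_five_point_hand_example(self):
        # x ranks: [1,2,3,4,5]; y = [10, 30, 20, 50, 40] -> ranks [1,3,2,5,4]
        # Pearson of ranks: 1 - 6*sum(d^2)/(n(n^2-1)) = 1 - 6*4/120 = 0.8
        vals = np.column_stack([[1.0, 2, 3, 4, 5], [10.0, 30, 20, 50, 40]])
        X = ExpressionMatrix(vals, [f"c{i}" for i in range(5)], ["x", "y"])
        table = spearman_tf_target(X, [("x", "y")])
        assert table.loc[0, "rho"] == pytest.approx(0.8)

    def test_missing_gene_rejected(self, small_matrix):
        with pytest.raises(ValueError, match="nope"):
            spearman_tf_target(small_matrix, [("g0", "nope")])
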