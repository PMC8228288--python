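"""Metrics, PR/auPR, cross-validation machinery, balance analysis."""

import itertools

import numpy as np
import pytest
from sklearn.metrics import average_precision_score

from snggat import (
    ConfusionCounts,
    SignedGraph,
    SyntheticConfig,
    TrainConfig,
    balance_satisfaction,
    build_adjacency,
    confusion,
    crossval,
    generate,
    metrics,
    pr_curve,
    split_k_fold,
    triangle_balance_census,
)
from snggat.evaluation import enumerate_triangles


class TestConfusion:
    def test_enumerated_four_pairs(self):
        c = confusion([1, 1, -1, -1], [1, -1, -1, 1])
        assert (c.tp, c.fp, c.tn, c.fn) == (1, 1, 1, 1)

    def test_perfect_prediction(self):
        c = confusion([1, -1, 1], [1, -1, 1])
        assert c.fp == 0 and c.fn == 0

    def test_total_inversion(self):
        c = confusion([-1, 1], [1, -1])
        assert c.tp == 0 and c.tn == 0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            confusion([1], [1, -1])

    @pytest.mark.parametrize("seed", range(10))
    def test_against_independent_counting(self, seed):
        rng = np.random.default_rng(seed)
        pred = rng.choice([-1, 1], size=50)
        true = rng.choice([-1, 1], size=50)
        c = confusion(pred, true)
        ref = {"tp": 0, "fp": 0, "tn": 0, "fn": 0}
        for p, t in zip(pred, true):
            key = ("t" if p == t else "f") + ("p" if p == 1 else "n")
            ref[key] += 1
        assert (c.tp, c.fp, c.tn, c.fn) == (ref["tp"], ref["fp"], ref["tn"], ref["fn"])
        assert c.total == 50


class TestMetrics:
    def test_direct_arithmetic(self):
        acc, prec, rec = metrics(ConfusionCounts(tp=3, fp=1, tn=4, fn=2))
        assert (acc, prec, rec) == (0.7, 0.75, 0.6)

    def test_all_positive_correct(self):
        assert metrics(ConfusionCounts(5, 0, 0, 0)) == (1.0, 1.0, 1.0)

    def test_undefined_precision_is_none_not_zero(self):
        acc, prec, rec = metrics(ConfusionCounts(tp=0, fp=0, tn=3, fn=2))
        assert prec is None and acc == 0.6 and rec == 0.0


class TestPrCurve:
    def test_perfect_ranking(self):
        _, _, au = pr_curve([0.9, 0.8, 0.2, 0.1], [1, 1, -1, -1])
        assert au == 1.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            pr_curve([0.5, 0.4], [1, 1])

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exhaustive_threshold_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 11))
        scores = np.round(rng.normal(size=n), 2)   # rounded to force ties
        labels = rng.choice([-1, 1], size=n)
        if (labels == 1).all() or (labels == -1).all():
            labels[0] *= -1
        _, _, au = pr_curve(scores, labels)
        # oracle: step through each distinct threshold, accumulate AP terms
        expected = 0.0
        prev_recall = 0.0
        n_pos = (labels == 1).sum()
        for thr in sorted(set(scores), reverse=True):
            sel = scores >= thr
            tp = np.sum(sel & (labels == 1))
            prec = tp / sel.sum()
            rec = tp / n_pos
            expected += (rec - prev_recall) * prec
            prev_recall = rec
        assert au == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_sklearn_average_precision(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.normal(size=40)
        labels = rng.choice([-1, 1], size=40)
        _, _, au = pr_curve(scores, labels)
        assert au == pytest.approx(average_precision_score(labels == 1, scores), abs=1e-12)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(1)
        scores = rng.normal(size=30)
        labels = rng.choice([-1, 1], size=30)
        _, _, au1 = pr_curve(scores, labels)
        _, _, au2 = pr_curve(np.exp(3 * scores), labels)
        assert au1 == pytest.approx(au2, abs=1e-12)

    def test_random_scores_balanced_labels_near_half(self):
        rng = np.random.default_rng(0)
        n = 4000
        labels = np.repeat([1, -1], n // 2)
        _, _, au = pr_curve(rng.normal(size=n), labels)
        assert au == pytest.approx(0.5, abs=0.05)


@pytest.fixture(scope="module")
def graph100():
    g, _ = generate(SyntheticConfig(n_nodes=40, density=0.2, noise=0.1, seed=0))
    return g


class TestSplitKFold:

    def test_partition_contract(self, graph100):
        splits = split_k_fold(graph100, k=5, seed=0)
        tests = [set(s.test_edges) for s in splits]
        assert sum(len(t) for t in tests) == graph100.n_edges
        for a, b in itertools.combinations(tests, 2):
            assert not a & b
        assert set().union(*tests) == set(graph100.edges)

    def test_same_seed_identical_folds(self, graph100):
        s1 = split_k_fold(graph100, k=5, seed=3)
        s2 = split_k_fold(graph100, k=5, seed=3)
        assert [s.test_edges for s in s1] == [s.test_edges for s in s2]

    def test_stratified_by_sign(self, graph100):
        signs = np.array([s for _, _, s in graph100.edges])
        pos_frac = (signs == 1).mean()
        for split in split_k_fold(graph100, k=5, seed=1):
            te = np.array([s for _, _, s in split.test_edges])
            expected_pos = pos_frac * len(te)
            assert abs((te == 1).sum() - expected_pos) <= 1.0

    def test_too_few_edges_rejected(self):
        g = SignedGraph.from_edges([("a", "b", 1), ("b", "c", -1)])
        with pytest.raises(ValueError):
            split_k_fold(g, k=5)


class TestCrossval:
    def test_deterministic_and_well_formed(self):
        g, _ = generate(SyntheticConfig(n_nodes=30, density=0.3, noise=0.0, seed=4))
        cfg = TrainConfig(dims=(6, 3), heads=(1, 1), epochs=20, seed=0)
        r1 = crossval(g, k=3, repeats=2, config=cfg, seed=7)
        r2 = crossval(g, k=3, repeats=2, config=cfg, seed=7)
        assert len(r1.folds) == 3
        assert [f.accuracy for f in r1.folds] == [f.accuracy for f in r2.folds]
        mean, sd = r1.summary()["accuracy"]
        assert mean == pytest.approx(np.mean([f.accuracy for f in r1.folds]))
        assert "fold" in r1.to_text()


class TestBalanceSatisfaction:
    def test_two_faction_network_fully_balanced(self):
        g, _ = generate(SyntheticConfig(n_nodes=30, density=0.4, noise=0.0, seed=2))
        assert balance_satisfaction(build_adjacency(g)) == 1.0

    def test_frustrated_triangle_contradicts_every_route(self):
        g = SignedGraph.from_edges([("a", "b", 1), ("a", "c", 1), ("b", "c", -1)])
        assert balance_satisfaction(build_adjacency(g)) == 0.0

    def test_global_sign_flip_breaks_faction_consistency(self):
        # flipping every sign makes within-faction edges negative: each
        # length-2 route then votes against its edge
        g, _ = generate(SyntheticConfig(n_nodes=30, density=0.4, noise=0.0, seed=2))
        A = build_adjacency(g)
        flipped = -A
        np.fill_diagonal(flipped, 1)
        assert balance_satisfaction(flipped) < 0.5

    def test_random_signs_near_half(self):
        rng = np.random.default_rng(0)
        n = 60
        A = np.sign(rng.normal(size=(n, n))).astype(np.int64)
        A = np.triu(A, 1)
        A = A + A.T + np.eye(n, dtype=np.int64)
        assert balance_satisfaction(A) == pytest.approx(0.5, abs=0.1)

    def test_no_evaluable_edges_rejected(self):
        g = SignedGraph.from_edges([("a", "b", 1)])
        with pytest.raises(ValueError):
            balance_satisfaction(build_adjacency(g))

    @pytest.mark.parametrize("seed", range(5))
    def test_route_length_3_matches_path_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = 7
        A = np.triu(rng.choice([-1, 0, 0, 1], size=(n, n)), 1)
        A = A + A.T
        from snggat.evaluation import _signed_route_counts
        got = _signed_route_counts(A, 3)
        ref = np.zeros((n, n), dtype=np.int64)
        for i in range(n):
            for j in range(n):
                for w1 in range(n):
                    for w2 in range(n):
                        if len({i, j, w1, w2}) == 4:
                            ref[i, j] += A[i, w1] * A[w1, w2] * A[w2, j]
        assert np.array_equal(got, ref)


class TestTriangleCensus:
    def test_known_patterns(self):
        # all-positive and one-positive/two-negative triangles are balanced;
        # two-positive/one-negative and all-negative are unbalanced
        cases = [((1, 1, 1), (1, 0)), ((1, -1, -1), (1, 0)),
                 ((1, 1, -1), (0, 1)), ((-1, -1, -1), (0, 1))]
        for signs, expected in cases:
            g = SignedGraph.from_edges([
                ("a", "b", signs[0]), ("b", "c", signs[1]), ("a", "c", signs[2])])
            assert triangle_balance_census(build_adjacency(g)) == expected

    def test_edgeless_graph(self):
        assert triangle_balance_census(np.eye(4, dtype=int)) == (0, 0)

    def test_all_positive_k4(self):
        A = np.ones((4, 4), dtype=np.int64)
        assert triangle_balance_census(A) == (4, 0)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 8
        A = np.triu(rng.choice([-1, 0, 1], size=(n, n)), 1)
        A = A + A.T + np.eye(n, dtype=np.int64)
        tri = list(enumerate_triangles(A))
        expected = (sum(1 for *_, s in tri if s > 0), sum(1 for *_, s in tri if s < 0))
        assert triangle_balance_census(A) == expected
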