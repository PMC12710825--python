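import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from remo import (
    GenomicInterval,
    ModuleSet,
    RegionSet,
    assemble_modules,
    broad_cluster,
    build_topk_graph,
    coaccessibility,
    discover_modules,
    distance_kernel,
    leiden_cpm,
    prepare_contacts,
    score_pairs,
    tmm_factors,
)
from remo.discovery import CoAccessGraph, clip_columns


def naive_tmm(X, trim_m=0.30, trim_a=0.05):
    """Independent straight-line reimplementation of the TMM recipe."""
    X = np.asarray(X, float)
    q75 = np.array([np.quantile(X[:, j], 0.75) for j in range(X.shape[1])])
    ref = int(np.argmin(np.abs(q75 - q75.mean())))
    N = X.sum(axis=0)
    f = []
    for k in range(X.shape[1]):
        pos = (X[:, k] > 0) & (X[:, ref] > 0)
        yk, yr = X[pos, k], X[pos, ref]
        M = np.log2(yk / yr)
        A = 0.5 * np.log2(yk * yr)
        w = (N[k] - yk) / (N[k] * yk) + (N[ref] - yr) / (N[ref] * yr)
        w = np.maximum(w, 1e-12)
        n = len(M)
        from scipy.stats import rankdata

        rM, rA = rankdata(M), rankdata(A)
        keep = (rM > n * trim_m) & (rM <= n * (1 - trim_m))
        keep &= (rA > n * trim_a) & (rA <= n * (1 - trim_a))
        if not keep.any():
            keep[:] = True
        f.append(2.0 ** (np.sum(M[keep] / w[keep]) / np.sum(1 / w[keep])))
    f = np.array(f)
    return f / np.exp(np.mean(np.log(f)))


class TestTmm:
    def test_identical_columns_factor_one(self):
        col = np.abs(np.random.default_rng(0).normal(5, 1, 50))
        f = tmm_factors(np.column_stack([col, col]))
        np.testing.assert_allclose(f, [1.0, 1.0])

    def test_doubled_column_closed_form(self):
        col = np.abs(np.random.default_rng(1).normal(5, 1, 100))
        f = tmm_factors(np.column_stack([col, 2 * col]))
        np.testing.assert_allclose(f, [2**-0.5, 2**0.5], rtol=1e-10)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_independent_reimplementation(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.gamma(2.0, 2.0, size=(200, 5)) * rng.uniform(0.5, 2.0, 5)
        np.testing.assert_allclose(tmm_factors(X), naive_tmm(X), rtol=1e-10)

    def test_all_zero_column_errors(self):
        with pytest.raises(ValueError):
            tmm_factors(np.array([[1.0, 0.0], [2.0, 0.0]]))


class TestClipColumns:
    def test_quantile_oracle(self):
        col = np.arange(1.0, 101.0)
        clipped = clip_columns(col[:, None], 0.90)
        expected_threshold = np.quantile(col, 0.90)  # 90.1 by linear interpolation
        assert clipped.max() == pytest.approx(expected_threshold)
        np.testing.assert_array_equal(clipped[col <= expected_threshold, 0], col[col <= expected_threshold])


class TestBroadCluster:
    def test_two_disjoint_blocks(self):
        rng = np.random.default_rng(2)
        block1 = np.zeros((20, 10))
        block1[:, :5] = rng.gamma(3, 1, (20, 5))
        block2 = np.zeros((20, 10))
        block2[:, 5:] = rng.gamma(3, 1, (20, 5))
        labels = broad_cluster(np.vstack([block1, block2]), knn=10, seed=0)
        truth = [0] * 20 + [1] * 20
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_duplicated_cre_shares_label(self):
        rng = np.random.default_rng(3)
        row = rng.gamma(2, 1, 8)
        X = np.vstack([row] * 6 + [rng.gamma(2, 1, 8) * 10 for _ in range(6)])
        labels = broad_cluster(X, knn=4, seed=0)
        assert len(set(labels[:6])) == 1

    def test_argument_errors(self):
        with pytest.raises(ValueError):
            broad_cluster(np.ones((5, 5)), n_pcs=0)


class TestScoreComponents:
    def test_coaccessibility_examples(self):
        X = np.array([[1.0, 2, 3], [1, 2, 3], [3, 2, 1], [1, 2, 4]])
        assert coaccessibility(X, 0, 1) == 1.0
        assert coaccessibility(X, 0, 2) == 0.0  # negative clipped
        r = coaccessibility(X, 0, 3)
        assert r == pytest.approx(np.corrcoef([1, 2, 3], [1, 2, 4])[0, 1])
        assert r == pytest.approx(0.982, abs=1e-3)

    def test_zero_variance_row_gives_zero(self):
        X = np.array([[1.0, 1, 1], [1, 2, 3]])
        assert coaccessibility(X, 0, 1) == 0.0

    def test_distance_kernel(self):
        sigma = 500_000.0
        assert distance_kernel(0.0) == 1.0
        assert distance_kernel(sigma) == pytest.approx(np.exp(-0.5))
        xs = np.linspace(0, 2e6, 50)
        d = distance_kernel(xs)
        assert np.all(np.diff(d) < 0)
        with pytest.raises(ValueError):
            distance_kernel(1.0, sigma=0)

    def test_score_zero_when_anticorrelated(self):
        regions = [
            GenomicInterval("chr1", 0, 200),
            GenomicInterval("chr1", 10_000, 10_200),
        ]
        X = np.array([[1.0, 2, 3, 4], [4, 3, 2, 1]])
        assert score_pairs(X, regions) == []

    def test_score_arithmetic_identity(self):
        # R = 1 (identical rows), no contacts, D = exp(-x^2/2sigma^2)
        regions = [
            GenomicInterval("chr1", 0, 200),
            GenomicInterval("chr1", 499_900, 500_100),
        ]
        X = np.array([[1.0, 2, 3, 4], [2, 4, 6, 8]])
        [(i, j, s)] = score_pairs(X, regions)
        assert (i, j) == (0, 1)
        assert s == pytest.approx(distance_kernel(499_900.0))

    def test_random_instance_matches_component_oracle(self):
        rng = np.random.default_rng(4)
        n = 15
        mids = np.sort(rng.integers(0, 2_000_000, n))
        regions = [GenomicInterval("chr1", int(m), int(m) + 200) for m in mids]
        X = rng.gamma(2, 1, (n, 6))
        from remo.contacts import TABLE_COLUMNS

        rows = [
            ("chr1", 5000 * int(rng.integers(0, 400)), 5000 * int(rng.integers(0, 400)), float(rng.exponential()))
            for _ in range(80)
        ]
        cmap = prepare_contacts([pd.DataFrame(rows, columns=TABLE_COLUMNS)])["chr1"]
        got = {(i, j): s for i, j, s in score_pairs(X, regions, cmap)}
        from remo import contact_for_pair

        for i in range(n):
            for j in range(i + 1, n):
                a, b = regions[i], regions[j]
                x = abs(a.midpoint - b.midpoint)
                if x > 1e6:
                    assert (i, j) not in got
                    continue
                r = max(np.corrcoef(X[i], X[j])[0, 1], 0.0)
                s = r * (contact_for_pair(cmap, a, b) + distance_kernel(x))
                if s > 0:
                    assert got[(i, j)] == pytest.approx(s)
                else:
                    assert (i, j) not in got
                # S is bounded and symmetric by construction
                assert 0 <= s <= 2


class TestTopKGraph:
    def test_fewer_than_k_kept(self):
        pairs = [(0, 1, 1.0), (0, 2, 0.5), (0, 3, 0.2)]
        g = build_topk_graph(pairs, n_nodes=4, k=30)
        assert sorted(g.edges) == [(0, 1), (0, 2), (0, 3)]

    def test_star_with_leaf_rescue(self):
        # hub 0 with 40 leaves of distinct scores: hub keeps its top 30,
        # but every leaf keeps its only edge, so all 40 survive the union
        pairs = [(0, i, float(i)) for i in range(1, 41)]
        g = build_topk_graph(pairs, n_nodes=41, k=30)
        assert len(g.edges) == 40
        # intersection semantics would have kept exactly 30 for the hub
        hub_kept = sorted(pairs, key=lambda t: -t[2])[:30]
        assert len(hub_kept) == 30

    def test_exact_topk_when_leaves_saturated(self):
        # connect every leaf to a private far node so leaf budgets are used
        pairs = [(0, i, float(i)) for i in range(1, 41)]
        g = build_topk_graph(pairs, n_nodes=41, k=1)
        # k=1: hub keeps (0, 40); each leaf keeps its own hub edge -> all survive
        assert (0, 40) in g.edges
        assert len(g.edges) == 40

    def test_tie_break_smaller_partner(self):
        pairs = [(0, 2, 1.0), (0, 1, 1.0)]
        g = build_topk_graph(pairs, n_nodes=3, k=1)
        assert (0, 1) in g.edges

    def test_permutation_invariance(self):
        rng = np.random.default_rng(5)
        pairs = [
            (int(i), int(j), float(rng.random() + 0.01))
            for i in range(10)
            for j in range(i + 1, 10)
        ]
        g1 = build_topk_graph(pairs, 10, k=3)
        perm = rng.permutation(len(pairs))
        g2 = build_topk_graph([pairs[p] for p in perm], 10, k=3)
        assert sorted(g1.edges) == sorted(g2.edges)

    def test_k_validation(self):
        with pytest.raises(ValueError):
            build_topk_graph([], 2, k=0)


class TestLeidenCpm:
    def two_cliques(self, weak=0.01):
        edges, weights = [], []
        for offset in (0, 5):
            for a in range(5):
                for b in range(a + 1, 5):
                    edges.append((offset + a, offset + b))
                    weights.append(1.0)
        edges.append((0, 5))
        weights.append(weak)
        return CoAccessGraph(10, edges, weights)

    def test_two_cliques_recovered(self):
        labels = leiden_cpm(self.two_cliques(), resolution=0.5, seed=0)
        truth = [0] * 5 + [1] * 5
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_empty_graph_all_singletons(self):
        labels = leiden_cpm(CoAccessGraph(6, [], []), seed=0)
        assert len(set(labels)) == 6

    def test_deterministic_under_seed(self):
        g = self.two_cliques()
        a = leiden_cpm(g, seed=42)
        b = leiden_cpm(g, seed=42)
        np.testing.assert_array_equal(a, b)


class TestAssembleModules:
    def regions3(self):
        return RegionSet(
            [
                GenomicInterval("chr1", 0, 2, name="a"),  # midpoint 1 -> shift all by -1
                GenomicInterval("chr1", 100, 102, name="b"),
                GenomicInterval("chr1", 200, 202, name="c"),
            ]
        )

    def test_mean_pairwise_distance_hand_case(self):
        ms = assemble_modules([("chr1", [0, 1, 2], [0, 0, 0])], self.regions3())
        assert ms.stats["size"].tolist() == [3]
        assert ms.stats["mean_pairwise_distance"].iloc[0] == pytest.approx(400 / 3)

    def test_all_singletons(self):
        ms = assemble_modules([], self.regions3())
        assert ms.stats["size"].tolist() == [1, 1, 1]
        assert (ms.stats["mean_pairwise_distance"] == 0).all()
        assert len(set(ms.labels)) == 3

    def test_assignment_total_and_chrom_prefixed(self):
        regions = RegionSet(
            [
                GenomicInterval("chr1", 0, 10),
                GenomicInterval("chr1", 100, 110),
                GenomicInterval("chr2", 0, 10),
            ]
        )
        ms = assemble_modules([("chr1", [0, 1], [0, 0])], regions)
        assert len(ms.labels) == 3
        assert ms.labels[0] == ms.labels[1] != ms.labels[2]
        assert ms.labels[2].startswith("chr2_")

    def test_overlapping_assignment_errors(self):
        with pytest.raises(RuntimeError):
            assemble_modules(
                [("chr1", [0, 1], [0, 0]), ("chr1", [1, 2], [0, 0])], self.regions3()
            )

    def test_from_labels_rejects_cross_chrom_module(self):
        regions = RegionSet(
            [GenomicInterval("chr1", 0, 10), GenomicInterval("chr2", 0, 10)]
        )
        with pytest.raises(ValueError, match="spans"):
            ModuleSet.from_labels(regions, ["m1", "m1"])


class TestDiscoverModules:
    def test_planted_recovery_small_world(self, small_world):
        maps = prepare_contacts(small_world.contact_tables)
        ms = discover_modules(
            small_world.signal,
            small_world.accessibility,
            small_world.regions,
            maps,
            seed=1,
        )
        ari = adjusted_rand_score(small_world.module_assignment.to_numpy(), ms.labels)
        assert ari >= 0.9
        # total assignment, no module spans chromosomes
        assert len(ms.labels) == len(small_world.regions)
        for module, idx in ms.members().items():
            assert len({small_world.regions[i].chrom for i in idx}) == 1

    def test_deterministic_under_seed(self, small_world):
        maps = prepare_contacts(small_world.contact_tables)
        args = (small_world.signal, small_world.accessibility, small_world.regions, maps)
        a = discover_modules(*args, seed=5)
        b = discover_modules(*args, seed=5)
        assert a.labels == b.labels
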