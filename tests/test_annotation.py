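import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from remo import (
    annotate_clusters,
    annotation_accuracy,
    binarize_cumsum,
    decile_transform,
    module_celltype_scores,
    preranked_enrichment,
    signed_score,
    tau_index,
)


class TestBinarizeCumsum:
    def test_hand_computation(self):
        binary, threshold = binarize_cumsum([5, 4, 1])
        assert binary.tolist() == [1, 1, 0]
        assert threshold == 4

    def test_single_nonzero(self):
        binary, _ = binarize_cumsum([0, 7, 0])
        assert binary.tolist() == [0, 1, 0]

    def test_uniform_ties_all_set(self):
        binary, threshold = binarize_cumsum([1.0] * 10)
        assert binary.sum() == 10  # ties at the threshold all set to 1
        assert threshold == 1.0

    def test_zero_total(self):
        binary, _ = binarize_cumsum([0.0, 0.0])
        assert binary.tolist() == [0, 0]

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            binarize_cumsum([-1.0, 2.0])


class TestTau:
    @pytest.mark.parametrize(
        "row,expected",
        [([1, 0, 0, 0], 1.0), ([1, 1, 1, 1], 0.0), ([1, 1, 0, 0], 2 / 3)],
    )
    def test_formula_values(self, row, expected):
        assert tau_index(np.array([row]))[0] == pytest.approx(expected)

    def test_all_zero_row_gets_zero(self):
        assert tau_index(np.array([[0, 0, 0]]))[0] == 0.0

    def test_n_below_two_rejected(self):
        with pytest.raises(ValueError):
            tau_index(np.array([[1], [0]]))

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.lists(st.integers(0, 1), min_size=2, max_size=8),
            min_size=1,
            max_size=10,
        ).filter(lambda rows: len({len(r) for r in rows}) == 1)
    )
    def test_bounds_and_iff_properties(self, rows):
        X = np.array(rows)
        tau = tau_index(X)
        assert np.all((0 <= tau) & (tau <= 1))
        for t, row in zip(tau, X):
            assert (t == 1.0) == (row.sum() == 1)
            if row.sum() == X.shape[1]:
                assert t == 0.0


class TestDecileTransform:
    def test_ten_distinct(self):
        v = np.arange(1.0, 11.0)
        np.testing.assert_allclose(decile_transform(v), np.arange(0.1, 1.05, 0.1))

    def test_all_zero(self):
        assert decile_transform(np.zeros(5)).tolist() == [0] * 5

    def test_ties_share_decile(self):
        out = decile_transform(np.full(4, 3.0))
        assert len(set(out)) == 1 and out[0] > 0

    def test_zeros_stay_zero(self):
        out = decile_transform([0.0, 5.0, 0.0, 1.0])
        assert out[0] == out[2] == 0.0
        assert out[1] == 1.0 and out[3] == 0.5


class TestModuleCelltypeScores:
    def test_single_cre_module(self):
        deciles = pd.DataFrame({"ct1": [0.7]}, index=["cre1"])
        deciles["ct2"] = 0.1
        scores, assigned = module_celltype_scores(
            deciles, np.array([1.0]), {"cre1": "m1"}, {"ct1": "T1", "ct2": "T2"}
        )
        assert scores.loc["m1", "T1"] == pytest.approx(0.7)

    def test_zero_tau_assigns_nothing(self):
        deciles = pd.DataFrame(
            {"ct1": [0.5, 0.6], "ct2": [0.2, 0.9]}, index=["a", "b"]
        )
        scores, assigned = module_celltype_scores(
            deciles, np.zeros(2), {"a": "m1", "b": "m2"}, {"ct1": "T1", "ct2": "T2"}
        )
        assert (scores.to_numpy() == 0).all()
        assert all(len(v) == 0 for v in assigned.values())

    @pytest.mark.parametrize("seed", range(2))
    def test_matches_double_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        cres = [f"cre{i}" for i in range(30)]
        cts = [f"ct{i}" for i in range(6)]
        deciles = pd.DataFrame(rng.integers(0, 11, (30, 6)) / 10.0, index=cres, columns=cts)
        tau = rng.random(30)
        modules = {c: f"m{i % 5}" for i, c in enumerate(cres)}
        # two columns share one term -> averaged
        terms = {ct: (f"T{j}" if j < 5 else "T4") for j, ct in enumerate(cts)}
        scores, _ = module_celltype_scores(deciles, tau, modules, terms)
        for m in {f"m{i}" for i in range(5)}:
            per_ct = {}
            for ct in cts:
                total = 0.0
                for i, c in enumerate(cres):
                    if modules[c] == m:
                        total += tau[i] * deciles.loc[c, ct]
                per_ct[ct] = total
            for term in {"T0", "T1", "T2", "T3", "T4"}:
                members = [ct for ct in cts if terms[ct] == term]
                expected = np.mean([per_ct[ct] for ct in members])
                assert scores.loc[m, term] == pytest.approx(expected)

    def test_invariant_to_cre_and_column_order(self):
        rng = np.random.default_rng(11)
        cres = [f"cre{i}" for i in range(12)]
        deciles = pd.DataFrame(
            rng.integers(0, 11, (12, 4)) / 10.0, index=cres, columns=list("abcd")
        )
        tau = pd.Series(rng.random(12), index=cres)
        modules = {c: f"m{i % 3}" for i, c in enumerate(cres)}
        terms = {c: f"T_{c}" for c in "abcd"}
        s1, _ = module_celltype_scores(deciles, tau, modules, terms)
        perm = rng.permutation(12)
        s2, _ = module_celltype_scores(
            deciles.iloc[perm, ::-1], tau.iloc[perm], modules, terms
        )
        pd.testing.assert_frame_equal(s1, s2.loc[s1.index, s1.columns])


class TestSignedScore:
    @pytest.mark.parametrize(
        "log2fc,p,expected", [(1.5, 0.01, 2.0), (-2.0, 0.001, -3.0), (1.0, 1.0, 0.0), (0.0, 0.01, 0.0)]
    )
    def test_examples(self, log2fc, p, expected):
        assert signed_score(log2fc, p) == pytest.approx(expected)

    def test_zero_p_floored_with_warning(self):
        with pytest.warns(UserWarning):
            r = signed_score(1.0, 0.0)
        assert r == pytest.approx(300.0)


class TestPrerankedEnrichment:
    def ranked(self, seed=0, n=200):
        rng = np.random.default_rng(seed)
        return pd.Series(rng.normal(0, 1, n), index=[f"m{i}" for i in range(n)])

    def test_planted_top_set_significant(self):
        ranked = self.ranked()
        top = list(ranked.sort_values(ascending=False).index[:10])
        res = preranked_enrichment(
            ranked, {"planted": top}, n_perm=1000, seed=1, padj_cutoff=None
        )
        row = res.set_index("term").loc["planted"]
        assert row["nes"] > 0
        assert row["padj"] <= 0.05

    def test_all_zero_scores_handled(self):
        ranked = pd.Series(0.0, index=[f"m{i}" for i in range(50)])
        res = preranked_enrichment(
            ranked, {"t": ["m1", "m2", "m3"]}, n_perm=200, seed=0, padj_cutoff=None
        )
        assert res["es"].iloc[0] == 0.0
        assert res["pval"].iloc[0] == 1.0

    def test_es_matches_gseapy_reference(self):
        gseapy = pytest.importorskip("gseapy")
        ranked = self.ranked(seed=5, n=100)
        rng = np.random.default_rng(9)
        members = list(rng.choice(ranked.index, 12, replace=False))
        ours = preranked_enrichment(
            ranked, {"set": members}, n_perm=200, seed=0, padj_cutoff=None
        )
        rnk = ranked.sort_values(ascending=False).rename_axis("gene").reset_index()
        ref = gseapy.prerank(
            rnk=rnk, gene_sets={"set": members}, permutation_num=100, seed=0,
            min_size=1, max_size=500, outdir=None, no_plot=True, threads=1,
            verbose=False,
        ).res2d
        assert ours["es"].iloc[0] == pytest.approx(float(ref["ES"].iloc[0]), abs=1e-9)

    def test_pvalues_uniform_under_null(self):
        """Type-I error calibration: random term sets give ~5% rejections."""
        ranked = self.ranked(seed=42)
        rng = np.random.default_rng(7)
        pvals = []
        for i in range(300):
            members = list(rng.choice(ranked.index, 15, replace=False))
            res = preranked_enrichment(
                ranked, {"t": members}, n_perm=500, seed=1000 + i, padj_cutoff=None
            )
            pvals.append(res["pval"].iloc[0])
        frac = np.mean(np.asarray(pvals) <= 0.05)
        assert 0.02 <= frac <= 0.08
        from scipy.stats import kstest

        assert kstest(pvals, "uniform").pvalue > 0.01

    def test_empty_universe_errors(self):
        with pytest.raises(ValueError):
            preranked_enrichment(pd.Series(dtype=float), {"t": ["x"]}, n_perm=100)


class TestAnnotateClusters:
    def diff_for(self, up_modules, all_modules, rng):
        rows = []
        for m in all_modules:
            if m in up_modules:
                rows.append((m, 2.0 + rng.normal(0, 0.1), 10.0 ** -rng.uniform(4, 8)))
            else:
                rows.append((m, rng.normal(0, 0.2), rng.uniform(0.2, 1.0)))
        return pd.DataFrame(rows, columns=["module", "log2fc", "pval"])

    def test_planted_term_is_top1(self):
        rng = np.random.default_rng(0)
        modules = [f"m{i}" for i in range(120)]
        term_sets = {f"T{j}": modules[j * 12 : (j + 1) * 12] for j in range(10)}
        diff = {"c0": self.diff_for(set(term_sets["T3"]), modules, rng)}
        out = annotate_clusters(diff, term_sets, n_perm=500, seed=2)
        assert out["c0"][0] == "T3"

    def test_tissue_restriction_removes_term(self):
        rng = np.random.default_rng(1)
        modules = [f"m{i}" for i in range(60)]
        term_sets = {"Tin": modules[:10], "Tout": modules[10:20]}
        diff = {"c0": self.diff_for(set(modules[10:20]), modules, rng)}
        out = annotate_clusters(
            diff, term_sets, tissue="tiss", tissue_terms={"tiss": ["Tin"]},
            n_perm=300, seed=0, padj_cutoff=None,
        )
        assert "Tout" not in out["c0"]

    def test_unknown_tissue_errors(self):
        with pytest.raises(ValueError):
            annotate_clusters({}, {"T": ["m"]}, tissue="nope", tissue_terms={"t": []})

    def test_accuracy_helper(self):
        preds = {"c0": ["A", "B"], "c1": ["B", "C"], "c2": ["C"]}
        ref = {"c0": "A", "c1": "C", "c2": "X"}
        assert annotation_accuracy(preds, ref, top=1) == pytest.approx(1 / 3)
        assert annotation_accuracy(preds, ref, top=3) == pytest.approx(2 / 3)
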