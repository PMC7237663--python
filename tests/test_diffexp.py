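"""Rank-sum and logistic LR tests, fold-changes, BH, and the gated contrast."""

import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from scipy import stats

import atlaspipe as ap
from atlaspipe.diffexp import (
    DEThresholds,
    bh_fdr,
    de_contrast,
    log_fold_change,
    lr_test,
    pct_expressed,
    wilcoxon_rank_sum,
)
from atlaspipe.io_formats import ValidationError


def exact_rank_sum_p(a, b, alternative="two_sided"):
    """Independent oracle: full enumeration of rank assignments."""
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    n_a = len(a)
    obs = ranks[:n_a].sum()
    sums = [sum(combo) for combo in itertools.combinations(ranks, n_a)]
    sums = np.array(sums)
    mean = sums.mean()
    if alternative == "greater":
        return float((sums >= obs).mean())
    if alternative == "less":
        return float((sums <= obs).mean())
    dev = abs(obs - mean)
    return float((np.abs(sums - mean) >= dev - 1e-12).mean())


class TestWilcoxon:
    def test_disjoint_small_groups_exact(self):
        """a=[1,2,3] vs b=[4,5,6]: 2 of the 20 rank assignments are as
        extreme, so the two-sided exact p is 0.1."""
        assert wilcoxon_rank_sum([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_complete_tie(self):
        assert wilcoxon_rank_sum([5.0], [5.0]) == 1.0

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            wilcoxon_rank_sum([], [1.0])

    def test_approximation_tracks_enumeration(self):
        """Asymptotic p within 0.01 of the enumeration oracle for distinct
        10+10 samples from one distribution."""
        from atlaspipe.diffexp import _rank_sum_matrix

        rng = np.random.default_rng(4)
        for _ in range(5):
            pooled = rng.permutation(20).astype(float)
            a, b = pooled[:10], pooled[10:]
            approx = _rank_sum_matrix(a[:, None], b[:, None], "two_sided")[0]
            exact = exact_rank_sum_p(a, b)
            assert abs(approx - exact) < 0.01

    def test_tie_fallback_stays_close_to_enumeration(self):
        """With heavy ties the tie-corrected approximation is still within a
        few hundredths of midrank enumeration."""
        rng = np.random.default_rng(40)
        for _ in range(5):
            a = rng.choice(6, size=10).astype(float)
            b = rng.choice(6, size=10).astype(float)
            assert abs(wilcoxon_rank_sum(a, b) - exact_rank_sum_p(a, b)) < 0.06

    def test_one_sided_directions(self):
        hi, lo = [5.0, 6, 7, 8], [1.0, 2, 3, 4]
        assert wilcoxon_rank_sum(hi, lo, "greater") < 0.05
        assert wilcoxon_rank_sum(hi, lo, "less") > 0.9


class TestLRTest:
    def test_constant_expression_uninformative(self):
        group = np.repeat([0, 1], 20)
        assert lr_test(np.ones(40), group) == 1.0

    def test_separating_expression_detected_via_penalized_path(self):
        rng = np.random.default_rng(5)
        group = np.repeat([0, 1], 100)
        expr = group + rng.normal(0, 1e-4, size=200)
        assert lr_test(expr, group) < 1e-10

    def test_confounded_expression_uniform_p(self):
        """When the group depends only on the covariate, the expression term
        (covariate plus independent noise) tests null: p uniform (KS at
        alpha=0.01 over 500 replicates)."""
        rng = np.random.default_rng(6)
        pvals = []
        for _ in range(500):
            z = rng.normal(size=150)
            expr = z + rng.normal(0, 0.5, size=150)
            group = (rng.random(150) < 1 / (1 + np.exp(-1.5 * z))).astype(int)
            if group.min() == group.max():
                continue
            pvals.append(lr_test(expr, group, covariates=z))
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_agrees_with_statsmodels(self):
        """Oracle: statsmodels Logit LR p on a clean, well-separated case."""
        import statsmodels.api as sm

        rng = np.random.default_rng(7)
        n = 150
        expr = rng.normal(size=n)
        cov = rng.normal(size=n)
        logit_p = 1 / (1 + np.exp(-(0.8 * expr + 0.5 * cov)))
        group = (rng.random(n) < logit_p).astype(int)
        ours = lr_test(expr, group, covariates=cov)
        X0 = sm.add_constant(cov)
        X1 = sm.add_constant(np.column_stack([cov, expr]))
        ll0 = sm.Logit(group, X0).fit(disp=0).llf
        ll1 = sm.Logit(group, X1).fit(disp=0).llf
        theirs = stats.chi2.sf(2 * (ll1 - ll0), df=1)
        assert ours == pytest.approx(theirs, rel=1e-4)

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            lr_test(np.arange(10.0), np.zeros(10))


class TestEffectSizes:
    def test_logfc_identity_and_antisymmetry(self):
        rng = np.random.default_rng(8)
        norm = sp.csr_matrix(np.log1p(rng.poisson(3.0, size=(20, 60)).astype(float)))
        a, b = np.arange(30), np.arange(30, 60)
        same = log_fold_change(norm, a, a)
        np.testing.assert_allclose(same, 0.0, atol=1e-12)
        np.testing.assert_allclose(
            log_fold_change(norm, a, b), -log_fold_change(norm, b, a), atol=1e-12
        )

    def test_logfc_approaches_log_ratio_at_scale(self):
        """Group means m and e*m at large m give a logFC near 1."""
        rng = np.random.default_rng(9)
        m = 400.0
        a_counts = rng.poisson(m * np.e, size=4000)
        b_counts = rng.poisson(m, size=4000)
        norm = sp.csr_matrix(np.log1p(np.concatenate([a_counts, b_counts]))[None, :].astype(float))
        lfc = log_fold_change(norm, np.arange(4000), np.arange(4000, 8000))
        assert abs(lfc[0] - 1.0) < 0.01

    def test_pct_expressed(self):
        counts = sp.csr_matrix(np.array([[0, 0, 0, 0], [1, 2, 3, 4], [1, 1, 0, 0]]))
        cols = np.arange(4)
        np.testing.assert_allclose(pct_expressed(counts, cols), [0.0, 1.0, 0.5])


class TestBH:
    def test_hand_computed_step_up(self):
        """[0.01, 0.02, 0.03, 0.04] all adjust to 0.04."""
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_fdr([0.3]), [0.3])

    def test_matches_brute_force_exactly(self):
        """Oracle: direct step-up definition, checked on random vectors."""

        def brute(p):
            p = np.asarray(p, dtype=float)
            m = p.size
            order = np.argsort(p, kind="stable")
            adj = np.empty(m)
            running = 1.0
            for rank in range(m, 0, -1):
                i = order[rank - 1]
                running = min(running, p[i] * m / rank)
                adj[i] = running
            return adj

        rng = np.random.default_rng(10)
        for _ in range(50):
            p = rng.random(rng.integers(1, 40))
            np.testing.assert_array_equal(bh_fdr(p), brute(p))

    def test_order_invariance(self):
        rng = np.random.default_rng(11)
        p = rng.random(25)
        perm = rng.permutation(25)
        np.testing.assert_allclose(bh_fdr(p)[perm], bh_fdr(p[perm]))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bh_fdr([0.5, 1.2])


class TestDeContrast:
    @pytest.fixture
    def toy(self):
        rng = np.random.default_rng(12)
        counts = rng.poisson(2.0, size=(30, 200))
        counts[0, :100] = rng.poisson(8.0, size=100)  # strong planted gene
        raw = sp.csr_matrix(counts)
        totals = counts.sum(axis=0)
        norm = sp.csr_matrix(np.log1p(counts / totals * 100.0))
        genes = [f"G{i}" for i in range(30)]
        return norm, raw, genes

    def test_weak_logfc_gene_not_tested(self, toy):
        """A gene below the 0.25 logFC gate is never tested, however well
        it separates the groups."""
        norm, raw, genes = toy
        table = de_contrast(norm, raw, genes, np.arange(100), np.arange(100, 200))
        weak = table[np.abs(table["logfc"]) <= 0.25]
        assert (~weak["tested"]).all()
        assert weak["p"].isna().all()

    def test_group_overlap_rejected(self, toy):
        norm, raw, genes = toy
        with pytest.raises(ValidationError):
            de_contrast(norm, raw, genes, np.arange(50), np.arange(40, 90))

    def test_relabel_flips_logfc_only(self, toy):
        norm, raw, genes = toy
        t1 = de_contrast(norm, raw, genes, np.arange(100), np.arange(100, 200))
        t2 = de_contrast(norm, raw, genes, np.arange(100, 200), np.arange(100))
        np.testing.assert_allclose(t1["logfc"], -t2["logfc"], atol=1e-12)
        pd.testing.assert_series_equal(t1["tested"], t2["tested"])
        np.testing.assert_allclose(
            t1.loc[t1["tested"], "p"], t2.loc[t2["tested"], "p"], rtol=1e-9
        )

    def test_cell_order_invariance(self, toy):
        norm, raw, genes = toy
        rng = np.random.default_rng(13)
        a, b = np.arange(100), np.arange(100, 200)
        t1 = de_contrast(norm, raw, genes, a, b)
        t2 = de_contrast(norm, raw, genes, rng.permutation(a), rng.permutation(b))
        np.testing.assert_allclose(t1["logfc"], t2["logfc"], atol=1e-12)
        np.testing.assert_allclose(
            t1.loc[t1["tested"], "p"], t2.loc[t2["tested"], "p"], rtol=1e-9
        )

    def test_planted_gene_flagged(self, toy):
        norm, raw, genes = toy
        table = de_contrast(norm, raw, genes, np.arange(100), np.arange(100, 200))
        row = table.iloc[0]
        assert row["tested"] and row["fdr"] < 0.05
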