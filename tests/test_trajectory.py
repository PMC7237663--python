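"""Lineage geometry, pseudotime association, smoothing, and the mixture."""

import numpy as np
import pytest
import scipy.sparse as sp
from scipy import stats

import atlaspipe as ap
from atlaspipe.io_formats import ValidationError
from atlaspipe.trajectory import (
    build_lineage,
    fit_gmm2,
    isolate_terminal,
    pseudotime_association,
    smooth_expression,
)


class TestBuildLineage:
    def test_collinear_geometry_exact_ordering(self):
        """Three collinear centroids with cells on the line: pseudotime
        ordering equals coordinate ordering exactly."""
        rng = np.random.default_rng(50)
        x = np.sort(rng.uniform(0, 30, size=300))
        coords = np.column_stack([x, np.zeros_like(x)])
        labels = np.array(["A"] * 100 + ["B"] * 100 + ["C"] * 100)
        path = build_lineage(coords, labels, root="A", end="C")
        assert path.populations == ["A", "B", "C"]
        # strictly increasing in x within the interior of the path
        order_pt = np.argsort(path.pseudotime, kind="stable")
        assert np.array_equal(order_pt, np.arange(300))

    def test_cells_at_centroids_get_cumulative_arclength(self):
        coords = np.array([[0.0, 0.0], [3.0, 4.0], [6.0, 8.0]])
        cells = np.repeat(coords, 5, axis=0)
        labels = np.repeat(["A", "B", "C"], 5)
        path = build_lineage(cells, labels, root="A", end="C")
        np.testing.assert_allclose(
            np.unique(path.pseudotime), [0.0, 5.0, 10.0], atol=1e-9
        )

    def test_cell_order_invariance(self):
        rng = np.random.default_rng(51)
        coords = rng.normal(size=(200, 3))
        coords[100:, 0] += 8.0
        labels = np.array(["A"] * 100 + ["B"] * 100)
        perm = rng.permutation(200)
        p1 = build_lineage(coords, labels, root="A", end="B").pseudotime
        p2 = build_lineage(coords[perm], labels[perm], root="A", end="B").pseudotime
        np.testing.assert_allclose(p1[perm], p2)

    def test_root_equals_end_rejected(self):
        coords = np.zeros((10, 2))
        labels = np.repeat(["A", "B"], 5)
        with pytest.raises(ValidationError):
            build_lineage(coords, labels, root="A", end="A")

    def test_off_path_cells_nan(self):
        """A population hanging off the main chain gets NaN pseudotime."""
        coords = np.array(
            [[0.0, 0.0]] * 20 + [[10.0, 0.0]] * 20 + [[20.0, 0.0]] * 20 + [[10.0, 15.0]] * 20
        )
        labels = np.array(["A"] * 20 + ["B"] * 20 + ["C"] * 20 + ["D"] * 20)
        path = build_lineage(coords, labels, root="A", end="C")
        assert "D" not in path.populations
        assert np.isnan(path.pseudotime[labels == "D"]).all()

    def test_inferred_pseudotime_tracks_planted(self, lineage_cells):
        """On the default synthetic lineage the projected pseudotime agrees
        with the planted continuum at Spearman >= 0.9."""
        lc = lineage_cells
        path = build_lineage(lc["coords"], lc["labels"], root=lc["chain"][0], end=lc["chain"][-1])
        rho = stats.spearmanr(path.pseudotime, lc["true_pseudotime"]).statistic
        assert rho >= 0.9


class TestPseudotimeAssociation:
    def test_linear_gene_flagged(self):
        rng = np.random.default_rng(52)
        n = 1000
        pt = rng.uniform(0, 10, n)
        linear = 0.5 * pt + rng.normal(0, 0.5, n)
        constant = rng.normal(2.0, 0.5, n)
        norm = sp.csr_matrix(np.vstack([linear, constant]))
        out = pseudotime_association(norm, ["LIN", "CONST"], pt)
        assert out.loc[out["gene"] == "LIN", "q"].iloc[0] < 1e-10
        assert out.loc[out["gene"] == "CONST", "p"].iloc[0] > 0.1
        assert not out.loc[out["gene"] == "CONST", "flagged"].iloc[0]

    def test_covariate_absorbs_group_shift(self):
        """A gene responding only to smoking, in a cohort where smokers sit
        later in pseudotime, is flagged without the covariate but absorbed
        by it."""
        rng = np.random.default_rng(53)
        n = 1000
        pt = rng.uniform(0, 10, n)
        smoker = (rng.random(n) < pt / 10.0).astype(float)  # habit tracks pt
        gene = 2.0 * smoker + rng.normal(0, 0.5, n)
        norm = sp.csr_matrix(gene[None, :])
        with_cov = pseudotime_association(norm, ["G"], pt, covariate=smoker)
        without = pseudotime_association(norm, ["G"], pt)
        assert not with_cov["flagged"].iloc[0]
        assert without["flagged"].iloc[0]

    def test_constant_pseudotime_rejected(self):
        norm = sp.csr_matrix(np.ones((1, 30)))
        with pytest.raises(ValidationError):
            pseudotime_association(norm, ["G"], np.ones(30))


class TestSmoothing:
    def test_constant_preserved(self):
        out = smooth_expression(np.full(200, 3.5), np.arange(200.0))
        np.testing.assert_allclose(out, 3.5)

    def test_linear_exact_away_from_ends(self):
        """Symmetric triangular weights reproduce a line exactly in the
        interior."""
        v = np.arange(300, dtype=float)
        out = smooth_expression(v, v, window=101)
        np.testing.assert_allclose(out[50:-50], v[50:-50], atol=1e-9)

    def test_output_within_input_range(self):
        rng = np.random.default_rng(54)
        v = rng.normal(size=500)
        out = smooth_expression(v, rng.random(500))
        assert out.min() >= v.min() - 1e-12
        assert out.max() <= v.max() + 1e-12

    def test_window_larger_than_data_rejected(self):
        with pytest.raises(ValidationError):
            smooth_expression(np.arange(10.0), np.arange(10.0), window=100)


def grid_search_gmm_loglik(x, n_grid=12):
    """Coarse brute-force maximum-likelihood oracle for the 2-mixture."""
    best = -np.inf
    mus = np.linspace(x.min(), x.max(), n_grid)
    sds = np.linspace(0.3 * x.std(), 1.5 * x.std(), 6)
    ws = np.linspace(0.1, 0.9, 9)
    for m1 in mus:
        for m2 in mus:
            if m2 < m1:
                continue
            for s1 in sds:
                for s2 in sds:
                    for w in ws:
                        ll = np.log(
                            w * stats.norm.pdf(x, m1, s1)
                            + (1 - w) * stats.norm.pdf(x, m2, s2)
                        ).sum()
                        best = max(best, ll)
    return best


class TestMixture:
    def test_recovers_separated_components(self):
        rng = np.random.default_rng(55)
        x = np.concatenate([rng.normal(2, 0.5, 1000), rng.normal(8, 0.5, 1000)])
        fit = fit_gmm2(x)
        assert abs(fit.means[0] - 2.0) < 0.1
        assert abs(fit.means[1] - 8.0) < 0.1
        assert fit.converged and fit.separated

    def test_loglik_nondecreasing(self):
        rng = np.random.default_rng(56)
        x = np.concatenate([rng.normal(0, 1, 300), rng.normal(4, 0.8, 200)])
        fit = fit_gmm2(x)
        diffs = np.diff(fit.ll_trajectory)
        assert (diffs >= -1e-9).all()

    def test_single_cluster_flagged_unseparated(self):
        rng = np.random.default_rng(57)
        x = rng.normal(5.0, 0.3, 400)
        fit = fit_gmm2(x)
        assert not fit.separated
        with pytest.raises(ValidationError):
            isolate_terminal(x, fit)

    def test_matches_grid_search_loglik(self):
        """EM reaches within 1% of a coarse grid-search ML oracle (the grid
        is coarse, so EM should do at least as well)."""
        rng = np.random.default_rng(58)
        x = np.concatenate([rng.normal(1, 0.6, 25), rng.normal(5, 0.8, 25)])
        fit = fit_gmm2(x)
        oracle = grid_search_gmm_loglik(x)
        assert fit.log_likelihood >= oracle - 0.01 * abs(oracle)

    def test_too_few_distinct_values_rejected(self):
        with pytest.raises(ValidationError):
            fit_gmm2(np.repeat([1.0, 2.0], 20))


class TestIsolateTerminal:
    def test_rule_arithmetic(self):
        """mu2=8, sd2=1 selects exactly the cells beyond 6."""
        from atlaspipe.trajectory import MixtureFit

        fit = MixtureFit(
            weights=(0.5, 0.5), means=(2.0, 8.0), sds=(0.5, 1.0),
            log_likelihood=0.0, iterations=1, converged=True,
        )
        pt = np.array([5.9, 6.0, 6.01, 7.5, 2.0])
        np.testing.assert_array_equal(
            isolate_terminal(pt, fit), [False, False, True, True, False]
        )

    def test_mask_monotone_in_pseudotime(self):
        rng = np.random.default_rng(59)
        x = np.concatenate([rng.normal(2, 0.5, 500), rng.normal(8, 0.5, 500)])
        fit = fit_gmm2(x)
        mask = isolate_terminal(x, fit)
        order = np.argsort(x)
        assert (np.diff(mask[order].astype(int)) >= 0).all()

    def test_planted_terminal_population_recovered(self, default_sim):
        """GMM + 2-SD rule on the planted continuum isolates the terminal
        secretory population at precision/recall >= 0.95."""
        _, annotations, truth = default_sim
        cells = truth.cells
        on = cells["true_pseudotime"].notna().to_numpy()
        pt = cells["true_pseudotime"].to_numpy()[on]
        fit = fit_gmm2(pt)
        mask = isolate_terminal(pt, fit)
        is_term = (cells["population"].to_numpy()[on] == truth.terminal_population)
        precision = (mask & is_term).sum() / mask.sum()
        recall = (mask & is_term).sum() / is_term.sum()
        assert precision >= 0.95
        assert recall >= 0.95
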