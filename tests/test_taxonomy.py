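"""Response taxonomy rules, enrichment matrix, composition and shares."""

import numpy as np
import pandas as pd
import pytest

import atlaspipe as ap
from atlaspipe.io_formats import CellAnnotations, CountMatrix, ValidationError
from atlaspipe.synthetic import DEFAULT_ROSTER
from atlaspipe.taxonomy import (
    TaxonomyThresholds,
    classify_response,
    marker_set_enrichment,
    proportion_shift,
    transcript_share,
)
import scipy.sparse as sp

ROSTER = [f"P{i}" for i in range(8)]


def make_tables(spec: dict) -> dict:
    """Build per-population DE tables from {gene: {pop: (logfc, fdr)}}.

    Populations not mentioned for a gene get a null row (tested, logfc 0,
    fdr 1); fdr None means untested.
    """
    genes = sorted(spec)
    tables = {}
    for pop in ROSTER:
        rows = []
        for g in genes:
            logfc, fdr = spec[g].get(pop, (0.0, 1.0))
            tested = fdr is not None
            rows.append(
                (g, logfc, 0.5, 0.5, fdr if tested else np.nan, fdr if tested else np.nan, tested)
            )
        tables[pop] = pd.DataFrame(
            rows, columns=["gene", "logfc", "pct_a", "pct_b", "p", "fdr", "tested"]
        )
    return tables


class TestClassifyResponse:
    def test_core_when_significant_in_five(self):
        spec = {"g1": {p: (1.0, 0.01) for p in ROSTER[:5]}}
        tax = classify_response(make_tables(spec), roster=ROSTER)
        assert tax.classes["up"]["g1"] == ("core", "")

    def test_unique_when_clear_everywhere_else(self):
        spec = {"g1": {"P0": (1.0, 0.001)}}
        for p in ROSTER[1:]:
            spec["g1"][p] = (0.1, 0.5)  # weak and non-significant elsewhere
        tax = classify_response(make_tables(spec), roster=ROSTER)
        assert tax.classes["up"]["g1"] == ("unique", "P0")

    def test_shadow_zone_blocks_uniqueness(self):
        """Significant in one population but with logFC 0.3 / FDR 0.1 in a
        second: neither clause of the exclusion holds there, so the gene is
        semi-unique."""
        spec = {"g1": {"P0": (1.0, 0.001), "P1": (0.3, 0.1)}}
        for p in ROSTER[2:]:
            spec["g1"][p] = (0.0, 1.0)
        tax = classify_response(make_tables(spec), roster=ROSTER)
        assert tax.classes["up"]["g1"] == ("semi_unique", "")

    def test_two_population_gene_is_semi_unique(self):
        spec = {"g1": {"P0": (1.0, 0.01), "P1": (1.0, 0.01)}}
        tax = classify_response(make_tables(spec), roster=ROSTER)
        assert tax.classes["up"]["g1"] == ("semi_unique", "")

    def test_untested_elsewhere_counts_as_not_affected(self):
        spec = {"g1": {"P0": (1.0, 0.001)}}
        for p in ROSTER[1:]:
            spec["g1"][p] = (0.0, None)  # gated out elsewhere
        tax = classify_response(make_tables(spec), roster=ROSTER)
        assert tax.classes["up"]["g1"] == ("unique", "P0")

    def test_directions_classified_independently(self):
        spec = {
            "g1": {p: (1.0, 0.01) for p in ROSTER[:5]},
        }
        spec["g1"].update({"P6": (-1.0, 0.01)})
        for p in ("P5", "P7"):
            spec["g1"][p] = (0.1, 0.9)
        tax = classify_response(make_tables(spec), roster=ROSTER)
        assert tax.classes["up"]["g1"][0] == "core"
        assert tax.classes["down"]["g1"][0] in ("unique", "semi_unique")

    def test_population_order_invariance(self):
        spec = {
            "g1": {p: (1.0, 0.01) for p in ROSTER[:5]},
            "g2": {"P3": (1.0, 0.001)},
        }
        for p in ROSTER:
            spec["g2"].setdefault(p, (0.05, 0.9))
        t1 = classify_response(make_tables(spec), roster=ROSTER)
        t2 = classify_response(make_tables(spec), roster=ROSTER[::-1])
        assert t1.classes == t2.classes

    def test_missing_roster_table_rejected(self):
        spec = {"g1": {"P0": (1.0, 0.01)}}
        tables = make_tables(spec)
        del tables["P7"]
        with pytest.raises(ValidationError):
            classify_response(tables, roster=ROSTER)

    def test_planted_taxonomy_recovered(self, default_sim, smoking_de_tables):
        """End-to-end: planted core and unique genes classify correctly."""
        _, _, truth = default_sim
        tax = classify_response(smoking_de_tables, roster=list(DEFAULT_ROSTER))
        core_up = set(tax.genes_in_class("up", "core"))
        core_dn = set(tax.genes_in_class("down", "core"))
        rec_core = len(core_up & set(truth.core_up)) + len(core_dn & set(truth.core_down))
        assert rec_core / (len(truth.core_up) + len(truth.core_down)) >= 0.90
        false_core = len(core_up - set(truth.core_up)) + len(core_dn - set(truth.core_down))
        assert false_core / max(len(core_up) + len(core_dn), 1) <= 0.02


class TestMarkerSetEnrichment:
    def test_identical_sets_extreme(self):
        universe = [f"G{i}" for i in range(2000)]
        markers = {"A": universe[:30]}
        response = {"R": universe[:30]}
        table = marker_set_enrichment(markers, response, universe)
        assert table["p"].iloc[0] < 1e-30
        assert bool(table["significant"].iloc[0])

    def test_zero_overlap_p_one(self):
        universe = [f"G{i}" for i in range(100)]
        table = marker_set_enrichment({"A": universe[:10]}, {"R": universe[50:60]}, universe)
        assert table["p"].iloc[0] == 1.0

    def test_null_overlap_not_significant(self):
        rng = np.random.default_rng(23)
        universe = [f"G{i}" for i in range(2000)]
        markers = {"A": list(rng.choice(universe, 50, replace=False))}
        response = {"R": list(rng.choice(universe, 50, replace=False))}
        table = marker_set_enrichment(markers, response, universe)
        assert not table["significant"].any()

    def test_empty_universe_rejected(self):
        with pytest.raises(ValidationError):
            marker_set_enrichment({"A": ["G1"]}, {"R": ["G1"]}, [])


class TestProportionShift:
    def _annotations(self, donor_pops: dict) -> CellAnnotations:
        rows = []
        for donor, (smoking, pops) in donor_pops.items():
            for i, p in enumerate(pops):
                rows.append((f"{donor}_{i}", donor, smoking, p))
        return CellAnnotations(
            pd.DataFrame(rows, columns=["cell_id", "donor", "smoking", "population"])
        )

    def test_shift_arithmetic(self):
        """Non-smokers uniformly 10% X; a smoker at 12% shifts +20%."""
        ns_cells = ["X"] * 10 + ["Y"] * 90
        s_cells = ["X"] * 12 + ["Y"] * 88
        ann = self._annotations(
            {"n1": ("never", ns_cells), "n2": ("never", ns_cells), "s1": ("heavy", s_cells)}
        )
        per_donor, summary = proportion_shift(ann)
        got = per_donor.query("population == 'X' and donor == 's1'")["shift_pct"].iloc[0]
        assert got == pytest.approx(20.0)

    def test_matching_proportions_zero_shift(self):
        cells = ["X"] * 10 + ["Y"] * 90
        ann = self._annotations({"n1": ("never", cells), "s1": ("heavy", cells)})
        per_donor, _ = proportion_shift(ann)
        assert np.allclose(per_donor["shift_pct"], 0.0)

    def test_permuted_labels_center_on_zero(self):
        """Randomly reassigning donors to smoking groups centers the mean
        shift near zero over permutations."""
        rng = np.random.default_rng(24)
        base = {f"d{i}": rng.multinomial(200, [0.3, 0.7]) for i in range(8)}
        means = []
        for _ in range(30):
            habits = rng.permutation(["never"] * 4 + ["heavy"] * 4)
            ann = self._annotations(
                {
                    d: (habits[i], ["X"] * counts[0] + ["Y"] * counts[1])
                    for i, (d, counts) in enumerate(base.items())
                }
            )
            _, summary = proportion_shift(ann)
            means.append(summary.query("population == 'X'")["mean_shift_pct"].iloc[0])
        assert abs(np.mean(means)) < 5.0

    def test_population_absent_from_nonsmokers_flagged(self):
        ann = self._annotations(
            {"n1": ("never", ["Y"] * 50), "s1": ("heavy", ["X"] * 5 + ["Y"] * 45)}
        )
        per_donor, summary = proportion_shift(ann)
        assert per_donor.query("population == 'X'")["undefined"].all()
        assert "X" not in set(summary["population"])


class TestTranscriptShare:
    def _setup(self):
        X = np.zeros((2, 6), dtype=int)
        X[0] = [10, 10, 0, 0, 0, 0]  # gene of interest: all in population A
        X[1] = [5, 5, 5, 5, 5, 5]
        counts = CountMatrix(sp.csr_matrix(X), ["GOI", "OTHER"], [f"c{i}" for i in range(6)])
        ann = CellAnnotations(
            pd.DataFrame(
                {
                    "cell_id": [f"c{i}" for i in range(6)],
                    "donor": "d1",
                    "smoking": "never",
                    "population": ["A", "A", "B", "B", "C", "C"],
                }
            )
        )
        return counts, ann

    def test_concentrated_gene_share(self):
        counts, ann = self._setup()
        share, fold = transcript_share(counts, ann, "GOI")
        assert share["A"] == pytest.approx(1.0)
        assert share["B"] == 0.0 and share["C"] == 0.0
        assert share.sum() == pytest.approx(1.0)

    def test_share_conservation_on_simulation(self, default_sim):
        counts, annotations, truth = default_sim
        share, _ = transcript_share(counts, annotations, truth.anchor_a)
        assert share.sum() == pytest.approx(1.0, abs=1e-12)

    def test_fold_ratio_limit(self):
        """Populations with per-cell means m and 2m at equal depth give a
        fold approaching 2 as the stabilizer becomes negligible."""
        rng = np.random.default_rng(25)
        n = 4000
        m = 200
        # the housekeeping row dwarfs the gene so both populations sequence
        # at essentially equal depth
        X = np.vstack(
            [
                np.concatenate([rng.poisson(2 * m, n), rng.poisson(m, n)]),
                np.full(2 * n, 100_000),
            ]
        ).astype(int)
        counts = CountMatrix(
            sp.csr_matrix(X), ["GOI", "OTHER"], [f"c{i}" for i in range(2 * n)]
        )
        ann = CellAnnotations(
            pd.DataFrame(
                {
                    "cell_id": counts.cell_ids,
                    "donor": "d1",
                    "smoking": "never",
                    "population": ["A"] * n + ["B"] * n,
                }
            )
        )
        _, fold = transcript_share(counts, ann, "GOI")
        assert fold.loc["A", "B"] == pytest.approx(2.0, rel=0.05)

    def test_unexpressed_gene_rejected(self):
        counts, ann = self._setup()
        counts.values[0, :] = 0
        with pytest.raises(ValidationError):
            transcript_share(counts, ann, "GOI")
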