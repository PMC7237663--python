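"""Core / unique / semi-unique smoking-response taxonomy and composition
statistics.

Per direction (up, down), a gene is *significant* in a population when its
smoker-versus-non-smoker contrast there has FDR < 0.05 with a log
fold-change of that sign.  A *core* response gene is significant in at
least five of the eight main populations; a *unique* gene is significant
in exactly one while showing |logFC| < 0.25 and/or FDR > 0.2 (or failing
the test gates altogether) in every other roster population; anything
significant somewhere but neither core nor unique is *semi-unique*.  The
two directions are classified independently.

Also here: hypergeometric enrichment of cell-type marker sets inside
response gene sets, donor-level composition shifts, and per-population
transcript share for a single gene.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .enrichment import hypergeom_upper
from .diffexp import bh_fdr
from .io_formats import CellAnnotations, CountMatrix, ValidationError

__all__ = [
    "TaxonomyThresholds",
    "ResponseTaxonomy",
    "classify_response",
    "marker_set_enrichment",
    "proportion_shift",
    "transcript_share",
]


@dataclass(frozen=True)
class TaxonomyThresholds:
    core_min: int = 5
    unique_logfc_max: float = 0.25
    unique_fdr_min: float = 0.2
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if min(self.core_min, self.unique_logfc_max, self.unique_fdr_min, self.alpha) <= 0:
            raise ValidationError("taxonomy thresholds must be positive")


@dataclass
class ResponseTaxonomy:
    """Per-direction gene classification; ``classes[direction][gene]`` is a
    ``(class, population)`` pair where population is empty unless unique."""

    classes: dict[str, dict[str, tuple[str, str]]]
    roster: list[str]

    def genes_in_class(self, direction: str, cls: str, population: str | None = None) -> list[str]:
        out = []
        for gene, (c, p) in self.classes[direction].items():
            if c == cls and (population is None or p == population):
                out.append(gene)
        return sorted(out)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (direction, gene, cls, pop)
            for direction, genes in self.classes.items()
            for gene, (cls, pop) in genes.items()
        ]
        return pd.DataFrame(rows, columns=["direction", "gene", "class", "population"])


def classify_response(
    de_tables: dict[str, pd.DataFrame],
    t: TaxonomyThresholds = TaxonomyThresholds(),
    roster: list[str] | None = None,
) -> ResponseTaxonomy:
    """Classify every gene significant somewhere, separately per direction.

    ``de_tables`` maps each roster population to its smoker-versus-
    non-smoker DE table (logFC convention: positive = up in smokers).
    """
    if roster is None:
        roster = sorted(de_tables)
    missing = [p for p in roster if p not in de_tables]
    if missing:
        raise ValidationError(f"missing DE table(s) for roster population(s) {missing}")
    genes = list(de_tables[roster[0]]["gene"])
    for p in roster:
        if list(de_tables[p]["gene"]) != genes:
            raise ValidationError("DE tables must share one gene universe in one order")

    indexed = {p: de_tables[p].set_index("gene") for p in roster}
    classes: dict[str, dict[str, tuple[str, str]]] = {"up": {}, "down": {}}
    for direction, sign in (("up", 1.0), ("down", -1.0)):
        sig = pd.DataFrame(
            {
                p: (
                    indexed[p]["tested"]
                    & (indexed[p]["fdr"] < t.alpha)
                    & (sign * indexed[p]["logfc"] > 0)
                )
                for p in roster
            }
        ).fillna(False)
        # the unique-gene exclusion clause, evaluated per other population:
        # weak logFC in this direction, or clearly non-significant, or gated out
        excl = pd.DataFrame(
            {
                p: (
                    (sign * indexed[p]["logfc"] < t.unique_logfc_max)
                    | (indexed[p]["fdr"] > t.unique_fdr_min)
                    | ~indexed[p]["tested"].astype(bool)
                )
                for p in roster
            }
        ).fillna(True)
        n_sig = sig.sum(axis=1)
        for gene in sig.index[n_sig > 0]:
            k = int(n_sig[gene])
            if k >= t.core_min:
                classes[direction][gene] = ("core", "")
                continue
            if k == 1:
                pop = sig.columns[sig.loc[gene]][0]
                others = [p for p in roster if p != pop]
                if all(excl.loc[gene, p] for p in others):
                    classes[direction][gene] = ("unique", pop)
                    continue
            classes[direction][gene] = ("semi_unique", "")
    return ResponseTaxonomy(classes=classes, roster=list(roster))


def marker_set_enrichment(
    marker_sets: dict[str, list[str]],
    response_sets: dict[str, list[str]],
    universe: list[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric over-representation of each marker set in each
    response set, BH-adjusted across the whole matrix.

    Returns one row per (marker_set, response_set) pair with the overlap,
    p, FDR, −log10 FDR and a significance flag at ``fdr < alpha``.
    """
    if not universe:
        raise ValidationError("empty universe")
    uni = set(universe)
    N = len(uni)
    rows = []
    for mname, mgenes in marker_sets.items():
        K = len(set(mgenes) & uni)
        for rname, rgenes in response_sets.items():
            draw = set(rgenes) & uni
            n = len(draw)
            k = len(set(mgenes) & draw)
            p = hypergeom_upper(k, K, n, N) if n and K else 1.0
            rows.append((mname, rname, k, K, n, p))
    table = pd.DataFrame(
        rows, columns=["marker_set", "response_set", "overlap", "set_size", "list_size", "p"]
    )
    table["fdr"] = bh_fdr(table["p"].to_numpy())
    table["neg_log10_fdr"] = -np.log10(np.maximum(table["fdr"], 1e-300))
    table["significant"] = table["fdr"] < alpha
    return table


def proportion_shift(annotations: CellAnnotations) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-smoker-donor percent shifts in population composition.

    Each donor's cells are converted to population proportions; a smoker
    donor's shift for a population is 100 × (donor proportion − mean
    non-smoker proportion) / (mean non-smoker proportion).  The summary is
    the mean and standard error of those shifts over smoker donors.
    Populations absent from every non-smoker are flagged undefined and
    excluded from the summary.
    """
    df = annotations.table.dropna(subset=["population"])
    smokers = df[df["smoking"] == "heavy"]["donor"].unique()
    nonsmokers = df[df["smoking"] == "never"]["donor"].unique()
    if len(smokers) == 0 or len(nonsmokers) == 0:
        raise ValidationError("need labeled cells from both smoking groups")
    prop = (
        df.groupby(["donor", "population"], observed=True).size().unstack(fill_value=0)
    )
    prop = prop.div(prop.sum(axis=1), axis=0)
    ns_mean = prop.loc[[d for d in nonsmokers if d in prop.index]].mean(axis=0)

    rows = []
    for d in smokers:
        if d not in prop.index:
            continue
        for pop in prop.columns:
            base = ns_mean[pop]
            if base == 0:
                rows.append((pop, d, np.nan, True))
            else:
                rows.append((pop, d, 100.0 * (prop.loc[d, pop] - base) / base, False))
    per_donor = pd.DataFrame(rows, columns=["population", "donor", "shift_pct", "undefined"])
    valid = per_donor[~per_donor["undefined"]]
    summary = (
        valid.groupby("population")["shift_pct"]
        .agg(mean_shift_pct="mean", sem=lambda x: x.std(ddof=1) / np.sqrt(len(x)))
        .reset_index()
    )
    return per_donor, summary


def transcript_share(
    counts: CountMatrix,
    annotations: CellAnnotations,
    gene: str,
    scale_total: float = 10_000.0,
) -> tuple[pd.Series, pd.DataFrame]:
    """Per-population share of a gene's total UMIs, and per-cell fold matrix.

    Share: population's summed raw UMIs over the grand total (shares sum to
    one exactly).  Fold: ratio of +1-stabilized population means of
    depth-normalized expression, fold[P, Q] = (mean_P + 1) / (mean_Q + 1).
    """
    gi = counts.gene_index([gene])[0]
    ann = annotations.aligned_to(counts.cell_ids).table
    pops = sorted(ann["population"].dropna().unique())
    raw = np.asarray(counts.values[gi, :].todense()).ravel()
    total = raw.sum()
    if total == 0:
        raise ValidationError(f"gene {gene!r} has no counts; shares undefined")
    depth = np.asarray(counts.values.sum(axis=0)).ravel().astype(float)
    norm = raw / np.maximum(depth, 1) * scale_total

    share = {}
    mean_norm = {}
    pop_labels = ann["population"].to_numpy()
    for p in pops:
        mask = pop_labels == p
        share[p] = raw[mask].sum() / total
        mean_norm[p] = norm[mask].mean() if mask.any() else np.nan
    share = pd.Series(share, name="share")
    fold = pd.DataFrame(
        {
            q: {p: (mean_norm[p] + 1.0) / (mean_norm[q] + 1.0) for p in pops}
            for q in pops
        }
    )
    return share, fold
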