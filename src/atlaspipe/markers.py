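"""Cluster-marker derivation and percentile-based cell characterization.

A gene is a marker of population P when it is significantly upregulated
(FDR < 0.05 after the logFC/detection gates) against *every* other
population in downsampled pairwise DE; large clusters are downsampled to
the median cluster size before testing.  Each marker's summary p is the
largest p across P's comparisons, re-adjusted by BH within P, which makes
the ranking conservative: a marker is only as good as its weakest contrast.

Signature scores are geometric means of log-normalized expression over the
top-ranked markers (25 by default, or as many as available).  Cells are
characterized by the percentile rule: labeled P when their P-score reaches
the 85th percentile of P-scores across all cells while every other
population's score stays below that population's own threshold (95th for
designated stringent populations).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .diffexp import DEThresholds, bh_fdr, de_contrast
from .io_formats import ValidationError
from .qc import geometric_mean_score

__all__ = [
    "CharacterizationRule",
    "pairwise_markers",
    "signature_score",
    "characterize_cells",
]


@dataclass(frozen=True)
class CharacterizationRule:
    own_percentile: float = 85.0
    other_percentile: float = 85.0
    top_n_markers: int = 100
    #: per-population percentile overrides (the stringency escape hatch used
    #: for transitional populations)
    overrides: tuple[tuple[str, float], ...] = ()

    def __post_init__(self) -> None:
        for p in (self.own_percentile, self.other_percentile, *(v for _, v in self.overrides)):
            if not 50 < p < 100:
                raise ValidationError("percentiles must lie in (50, 100)")


def pairwise_markers(
    normalized: sp.spmatrix,
    counts: sp.spmatrix,
    gene_ids: list[str],
    labels: np.ndarray,
    t: DEThresholds = DEThresholds(),
    seed: int = 0,
    *,
    test: str = "wilcoxon",
    covariates: np.ndarray | None = None,
    min_cells: int = 25,
) -> pd.DataFrame:
    """Derive markers for every sufficiently large population.

    Populations below ``min_cells`` are excluded with a warning column in
    the log; at least two must remain.  Downsampling to the median cluster
    size is seeded and done once per population, so reruns with the same
    seed give identical tables.

    Returns a table with columns population, gene, max_p, fdr,
    min_logfc, rank (dense from 1 by ascending FDR; ties broken by
    descending min_logfc, then gene name).
    """
    labels = np.asarray(labels)
    pops, counts_per = np.unique(labels, return_counts=True)
    eligible = [p for p, n in zip(pops, counts_per) if n >= min_cells]
    if len(eligible) < 2:
        raise ValidationError("need at least two populations with enough cells")

    rng = np.random.default_rng(seed)
    median_size = int(np.floor(np.median([np.sum(labels == p) for p in eligible])))
    subsample: dict[str, np.ndarray] = {}
    for p in sorted(eligible):
        idx = np.flatnonzero(labels == p)
        if idx.size > median_size:
            idx = np.sort(rng.choice(idx, size=median_size, replace=False))
        subsample[p] = idx

    rows = []
    for p in sorted(eligible):
        per_gene_p: np.ndarray | None = None
        per_gene_lfc: np.ndarray | None = None
        ok = np.ones(len(gene_ids), dtype=bool)
        for q in sorted(eligible):
            if q == p:
                continue
            cov = None
            if covariates is not None:
                joint = np.concatenate([subsample[p], subsample[q]])
                cov = np.atleast_2d(np.asarray(covariates, dtype=float))
                if cov.shape[0] != len(labels):
                    cov = cov.T
                cov = cov[joint]
            table = de_contrast(
                normalized, counts, gene_ids, subsample[p], subsample[q],
                t=t, test=test, covariates=cov,
            )
            sig_up = (
                table["tested"].to_numpy()
                & (table["logfc"].to_numpy() > 0)
                & (table["fdr"].to_numpy() < t.alpha_fdr)
            )
            ok &= sig_up
            pvec = np.where(sig_up, table["p"].to_numpy(), np.inf)
            lvec = np.where(sig_up, table["logfc"].to_numpy(), np.inf)
            per_gene_p = pvec if per_gene_p is None else np.maximum(per_gene_p, pvec)
            per_gene_lfc = lvec if per_gene_lfc is None else np.minimum(per_gene_lfc, lvec)
        marker_idx = np.flatnonzero(ok)
        if marker_idx.size == 0:
            continue
        max_p = per_gene_p[marker_idx]
        fdr = bh_fdr(max_p)
        sub = pd.DataFrame(
            {
                "population": p,
                "gene": [gene_ids[i] for i in marker_idx],
                "max_p": max_p,
                "fdr": fdr,
                "min_logfc": per_gene_lfc[marker_idx],
            }
        )
        sub = sub.sort_values(
            ["fdr", "min_logfc", "gene"], ascending=[True, False, True]
        ).reset_index(drop=True)
        sub["rank"] = np.arange(1, len(sub) + 1)
        rows.append(sub)
    if not rows:
        return pd.DataFrame(
            columns=["population", "gene", "max_p", "fdr", "min_logfc", "rank"]
        )
    return pd.concat(rows, ignore_index=True)


def _top_markers(marker_table: pd.DataFrame, population: str, top_n: int) -> list[str]:
    sub = marker_table[marker_table["population"] == population]
    if sub.empty:
        raise ValidationError(f"population {population!r} has no markers in the table")
    return list(sub.sort_values("rank")["gene"].head(top_n))


def signature_score(
    normalized: sp.spmatrix,
    gene_ids: list[str],
    marker_table: pd.DataFrame,
    population: str,
    top_n: int = 25,
) -> np.ndarray:
    """Geometric-mean score over the population's top markers, per cell.

    Uses the top ``top_n`` ranked markers, or as many as available when the
    population has fewer.
    """
    genes = _top_markers(marker_table, population, top_n)
    return geometric_mean_score(normalized, gene_ids, genes)


def characterize_cells(
    normalized: sp.spmatrix,
    gene_ids: list[str],
    marker_table: pd.DataFrame,
    rule: CharacterizationRule = CharacterizationRule(),
) -> pd.Series:
    """Label each cell by the exclusive-percentile marker rule.

    A cell is labeled P when its mean expression over P's top markers is at
    or above P's percentile threshold (computed across all cells) while
    every other population's score falls below that population's own
    threshold; anything else is unassigned (empty string).
    """
    pops = sorted(marker_table["population"].unique())
    if len(pops) < 2:
        raise ValidationError("need markers for at least two populations")
    overrides = dict(rule.overrides)
    lookup = {g: i for i, g in enumerate(gene_ids)}
    scores = np.zeros((normalized.shape[1], len(pops)))
    for j, p in enumerate(pops):
        genes = [g for g in _top_markers(marker_table, p, rule.top_n_markers) if g in lookup]
        sub = normalized[[lookup[g] for g in genes], :]
        if sp.issparse(sub):
            sub = sub.toarray()
        scores[:, j] = np.asarray(sub).mean(axis=0)
    own_cut = np.array(
        [np.percentile(scores[:, j], overrides.get(p, rule.own_percentile))
         for j, p in enumerate(pops)]
    )
    other_cut = np.array(
        [np.percentile(scores[:, j], overrides.get(p, rule.other_percentile))
         for j, p in enumerate(pops)]
    )
    labels = []
    for i in range(scores.shape[0]):
        above = scores[i] >= own_cut
        below_other = scores[i] < other_cut
        winners = [
            p
            for j, p in enumerate(pops)
            if above[j] and all(below_other[k] for k in range(len(pops)) if k != j)
        ]
        labels.append(winners[0] if len(winners) == 1 else "")
    return pd.Series(labels, name="characterized")
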