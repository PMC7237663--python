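"""Cell and gene quality-control filters, depth normalization, and the
geometric-mean expression scores used throughout the pipeline.

Cell filters run in a fixed order — doublet guard (99th-percentile gene or
UMI count), minimum detected genes (1500), mitochondrial fraction (40%) —
and a cell removed by several rules is attributed to the first.  Percentile
thresholds are computed once on the input and frozen for the pass.  Gene
filters remove symbols matching an excluded-prefix list (mitochondrial and
ribosomal families) and genes detected in under 0.1% of cells, where
"detected" always means raw UMI count > 0.

Variance stabilization is deliberately simple: depth normalization to a
fixed total (default 10,000) followed by log1p.  Downstream stages are rank-
or detection-based and insensitive to the variance-stabilization choice;
this keeps the pipeline deterministic and dependency-light.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .io_formats import CountMatrix, ValidationError

__all__ = [
    "QCThresholds",
    "QCReport",
    "filter_cells",
    "filter_genes",
    "normalize",
    "geometric_mean_score",
    "scale_unit",
    "DEFAULT_EXCLUDED_PREFIXES",
]

DEFAULT_EXCLUDED_PREFIXES = (
    "MTAT", "MT-", "MTCO", "MTCY", "MTERF", "MTND", "MTRF", "MTRN",
    "MRPL", "MRPS", "RPL", "RPS",
)


@dataclass(frozen=True)
class QCThresholds:
    min_genes_per_cell: int = 1500
    max_mito_fraction: float = 0.40
    upper_percentile: float = 99.0
    min_cell_fraction_per_gene: float = 0.001
    excluded_gene_prefixes: tuple[str, ...] = DEFAULT_EXCLUDED_PREFIXES

    def __post_init__(self) -> None:
        if not 0 < self.max_mito_fraction <= 1:
            raise ValidationError("max_mito_fraction must be in (0, 1]")
        if not 50 < self.upper_percentile < 100:
            raise ValidationError("upper_percentile must be in (50, 100)")


@dataclass
class QCReport:
    """Removal tallies per rule; removed + survivors equals the input size."""

    n_input: int = 0
    removed: dict[str, int] = field(default_factory=dict)
    survivors: int = 0
    thresholds: dict[str, float] = field(default_factory=dict)

    def check_conserved(self) -> bool:
        return self.n_input == self.survivors + sum(self.removed.values())


def filter_cells(
    counts: CountMatrix, mito_gene_mask: np.ndarray, t: QCThresholds
) -> tuple[CountMatrix, QCReport]:
    """Apply the ordered cell filters and report per-rule removals.

    Percentile thresholds (linear interpolation between order statistics)
    are computed on the input cells and not recomputed during the pass.
    """
    if counts.n_cells == 0 or counts.n_genes == 0:
        raise ValidationError("empty count matrix")
    mito_gene_mask = np.asarray(mito_gene_mask, dtype=bool)
    if mito_gene_mask.shape != (counts.n_genes,):
        raise ValidationError(
            f"mito mask length {mito_gene_mask.shape} does not match "
            f"{counts.n_genes} genes"
        )
    mat = counts.values.tocsc()
    genes_detected = np.asarray((mat > 0).sum(axis=0)).ravel()
    umi_total = np.asarray(mat.sum(axis=0)).ravel()
    mito_total = np.asarray(mat[mito_gene_mask, :].sum(axis=0)).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(umi_total > 0, mito_total / np.maximum(umi_total, 1), 0.0)

    gene_cut = np.percentile(genes_detected, t.upper_percentile, method="linear")
    umi_cut = np.percentile(umi_total, t.upper_percentile, method="linear")

    doublet = (genes_detected > gene_cut) | (umi_total > umi_cut)
    low_genes = ~doublet & (genes_detected < t.min_genes_per_cell)
    high_mito = ~doublet & ~low_genes & (mito_frac > t.max_mito_fraction)
    keep = ~(doublet | low_genes | high_mito)

    report = QCReport(
        n_input=counts.n_cells,
        removed={
            "doublet_guard": int(doublet.sum()),
            "min_genes": int(low_genes.sum()),
            "mito_fraction": int(high_mito.sum()),
        },
        survivors=int(keep.sum()),
        thresholds={"gene_count_cut": float(gene_cut), "umi_count_cut": float(umi_cut)},
    )
    return counts.subset_cells(keep), report


def filter_genes(counts: CountMatrix, t: QCThresholds) -> tuple[CountMatrix, QCReport]:
    """Remove excluded-prefix genes, then genes detected in too few cells."""
    symbols = counts.gene_ids
    prefix_hit = np.array(
        [any(g.startswith(p) for p in t.excluded_gene_prefixes) for g in symbols]
    )
    detected_cells = np.asarray((counts.values > 0).sum(axis=1)).ravel()
    min_cells = t.min_cell_fraction_per_gene * counts.n_cells
    rare = ~prefix_hit & (detected_cells < min_cells)
    keep = ~(prefix_hit | rare)
    report = QCReport(
        n_input=counts.n_genes,
        removed={"excluded_prefix": int(prefix_hit.sum()), "min_cell_fraction": int(rare.sum())},
        survivors=int(keep.sum()),
        thresholds={"min_cells": float(min_cells)},
    )
    return counts.subset_genes(keep), report


def normalize(counts: CountMatrix, scale_total: float = 10_000.0) -> sp.csr_matrix:
    """Depth-normalize each cell to ``scale_total`` counts, then log1p.

    Returns a sparse genes × cells matrix of log-normalized expression.
    Invariant to rescaling any cell's counts by a positive constant.
    """
    totals = np.asarray(counts.values.sum(axis=0)).ravel().astype(float)
    if (totals == 0).any():
        raise ValidationError("cannot normalize cells with zero total counts")
    mat = counts.values.astype(float).tocsc()
    scaled = mat @ sp.diags(scale_total / totals)
    scaled = scaled.tocsr()
    scaled.data = np.log1p(scaled.data)
    return scaled


def geometric_mean_score(
    normalized: sp.spmatrix,
    gene_ids: list[str],
    genes: list[str],
) -> np.ndarray:
    """Per-cell geometric mean of normalized expression over a gene panel.

    Computed as exp(mean(log(x + 1))) − 1 with a fixed +1 added to every
    normalized value so zeros are defined; a cell expressing none of the
    panel scores exactly 0.  Genes absent from the matrix are dropped with a
    warning; at least one must remain.
    """
    lookup = {g: i for i, g in enumerate(gene_ids)}
    present = [g for g in genes if g in lookup]
    missing = [g for g in genes if g not in lookup]
    if missing:
        warnings.warn(f"dropping {len(missing)} gene(s) absent from matrix: {missing[:5]}")
    if not present:
        raise ValidationError("no panel gene present in the matrix")
    rows = [lookup[g] for g in present]
    sub = normalized[rows, :]
    if sp.issparse(sub):
        sub = sub.toarray()
    return np.exp(np.log1p(np.asarray(sub)).mean(axis=0)) - 1.0


def scale_unit(values: np.ndarray) -> np.ndarray:
    """Affinely rescale to [0, 1]; rejects constant input."""
    values = np.asarray(values, dtype=float)
    lo, hi = values.min(), values.max()
    if hi == lo:
        raise ValidationError("cannot unit-scale a constant vector")
    return (values - lo) / (hi - lo)
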