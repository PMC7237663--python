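"""Mucin co-expression profiles and anchor-specific correlated gene programs.

Secretory cells are classed by raw-count positivity for the two anchor
mucins (MUC5AC / MUC5B analogs) into both / A-only / B-only / neither.
Within cells expressing both anchors (excluded-donor cells removed), each
gene's association with each anchor is measured by partial Spearman
correlation controlling for smoking habit: expression and anchor values
are rank-transformed, residualized on the ranked confounder by least
squares, and the residuals correlated; p comes from the t approximation
with n − 3 degrees of freedom.  BH-significant association with exactly
one anchor assigns the gene to that anchor's program; programs are ranked
by correlation strength, and smoking shifts in program scores are tested
with one-sided rank-sum tests in pre-declared directions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats

from .diffexp import bh_fdr, wilcoxon_rank_sum
from .io_formats import ValidationError

__all__ = [
    "coexpression_classes",
    "partial_spearman",
    "derive_programs",
    "program_shift_test",
]


def coexpression_classes(
    counts: sp.spmatrix,
    gene_ids: list[str],
    cells: np.ndarray,
    anchors: tuple[str, str],
    third: str | None = None,
) -> dict:
    """Classify cells by anchor positivity (raw count > 0).

    Returns per-cell classes and their proportions over the subset, plus
    the positivity rate of an optional third gene (SCGB1A1 analog).
    """
    lookup = {g: i for i, g in enumerate(gene_ids)}
    for a in anchors:
        if a not in lookup:
            raise ValidationError(f"anchor {a!r} not in matrix")
    sub = counts[:, np.asarray(cells)]
    a_pos = np.asarray((sub[lookup[anchors[0]], :] > 0).todense()).ravel()
    b_pos = np.asarray((sub[lookup[anchors[1]], :] > 0).todense()).ravel()
    classes = np.where(
        a_pos & b_pos, "both",
        np.where(a_pos, "A_only", np.where(b_pos, "B_only", "neither")),
    )
    n = classes.size
    proportions = {c: float((classes == c).sum()) / n for c in ("both", "A_only", "B_only", "neither")}
    out = {"classes": classes, "proportions": proportions}
    if third is not None:
        if third not in lookup:
            raise ValidationError(f"gene {third!r} not in matrix")
        t_pos = np.asarray((sub[lookup[third], :] > 0).todense()).ravel()
        out["third_positive_rate"] = float(t_pos.mean())
    return out


def _rank(v: np.ndarray) -> np.ndarray:
    return stats.rankdata(v, method="average")


def partial_spearman(
    x: np.ndarray, y: np.ndarray, z: np.ndarray
) -> tuple[float, float]:
    """Spearman correlation of ``x`` and ``y`` controlling for ``z``.

    All three are rank-transformed (average ranks on ties); ranked x and y
    are residualized on ranked z by least squares, and rho is the Pearson
    correlation of the residuals.  p uses the t approximation with n − 3
    degrees of freedom.  A constant confounder falls back to plain
    Spearman with a warning.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    z = np.asarray(z, dtype=float).ravel()
    n = x.size
    if n < 4:
        raise ValidationError("need at least 4 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("x and y must not be constant")
    if np.ptp(z) == 0:
        warnings.warn("constant confounder: falling back to plain Spearman")
        rho, p = stats.spearmanr(x, y)
        return float(rho), float(p)
    rx, ry, rz = _rank(x), _rank(y), _rank(z)
    design = np.column_stack([np.ones(n), rz])
    beta_x, *_ = np.linalg.lstsq(design, rx, rcond=None)
    beta_y, *_ = np.linalg.lstsq(design, ry, rcond=None)
    ex = rx - design @ beta_x
    ey = ry - design @ beta_y
    rho = float(np.corrcoef(ex, ey)[0, 1])
    df = n - 3
    rho_c = np.clip(rho, -0.9999999, 0.9999999)
    t = rho_c * np.sqrt(df / (1.0 - rho_c**2))
    p = float(2.0 * stats.t.sf(abs(t), df))
    return rho, p


def _partial_spearman_matrix(
    X: np.ndarray, y: np.ndarray, z: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise partial Spearman of every row of X against y, given z."""
    n = y.size
    ranks = np.apply_along_axis(_rank, 1, X)
    ry, rz = _rank(y), _rank(z)
    design = np.column_stack([np.ones(n), rz])
    Q, _ = np.linalg.qr(design)
    resid = lambda M: M - (M @ Q) @ Q.T  # rows are observations-in-columns
    EX = resid(ranks)
    ey = ry - Q @ (Q.T @ ry)
    num = EX @ ey
    den = np.sqrt((EX**2).sum(axis=1) * (ey**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.where(den > 0, num / den, 0.0)
    df = n - 3
    rho_c = np.clip(rho, -0.9999999, 0.9999999)
    t = rho_c * np.sqrt(df / (1.0 - rho_c**2))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return rho, p


def derive_programs(
    normalized: sp.spmatrix,
    counts: sp.spmatrix,
    gene_ids: list[str],
    cells: np.ndarray,
    anchors: tuple[str, str],
    smoking: np.ndarray,
    *,
    excluded: np.ndarray | None = None,
    min_rho_report: float = 0.15,
    alpha: float = 0.05,
    min_cells: int = 50,
) -> pd.DataFrame:
    """Assign genes to anchor-specific co-expression programs.

    ``cells`` indexes the secretory subset; ``smoking`` (boolean, aligned
    to ``cells``) is the confounder; ``excluded`` (boolean, aligned to
    ``cells``) removes excluded-donor cells.  Cells not expressing both
    anchors (raw count > 0) are dropped before correlation.  Returns one
    row per non-anchor gene with rho/p/FDR against each anchor, the
    program assignment in {A_specific, B_specific, both, none}, and a
    ``reportable`` flag at rho > ``min_rho_report``.
    """
    cells = np.asarray(cells)
    smoking = np.asarray(smoking, dtype=bool)
    if excluded is not None:
        keep = ~np.asarray(excluded, dtype=bool)
        cells, smoking = cells[keep], smoking[keep]
    lookup = {g: i for i, g in enumerate(gene_ids)}
    ia, ib = lookup[anchors[0]], lookup[anchors[1]]
    raw = counts[:, cells]
    both = np.asarray(
        ((raw[ia, :] > 0).multiply(raw[ib, :] > 0)).todense()
    ).ravel().astype(bool)
    cells, smoking = cells[both], smoking[both]
    if cells.size < min_cells:
        raise ValidationError(
            f"only {cells.size} eligible cells (< {min_cells}): too few for "
            "rank correlation at this scale"
        )
    sub = normalized[:, cells]
    dense = sub.toarray() if sp.issparse(sub) else np.asarray(sub)
    ya, yb = dense[ia], dense[ib]
    z = smoking.astype(float)
    rows = np.array([i for i in range(len(gene_ids)) if i not in (ia, ib)])
    X = dense[rows]
    # constant genes carry no rank signal: rho 0, p 1
    const = np.ptp(X, axis=1) == 0
    rho_a, p_a = _partial_spearman_matrix(X, ya, z)
    rho_b, p_b = _partial_spearman_matrix(X, yb, z)
    rho_a[const], p_a[const] = 0.0, 1.0
    rho_b[const], p_b[const] = 0.0, 1.0
    fdr_a = bh_fdr(p_a)
    fdr_b = bh_fdr(p_b)
    # program membership means positive co-expression with the anchor:
    # depth normalization couples every gene negatively to a highly
    # expressed anchor's swings, and those compositional anti-correlations
    # are not program genes
    sig_a = (fdr_a < alpha) & (rho_a > 0)
    sig_b = (fdr_b < alpha) & (rho_b > 0)
    assignment = np.where(
        sig_a & sig_b, "both",
        np.where(sig_a, "A_specific", np.where(sig_b, "B_specific", "none")),
    )
    return pd.DataFrame(
        {
            "gene": [gene_ids[i] for i in rows],
            "rho_a": rho_a,
            "p_a": p_a,
            "fdr_a": fdr_a,
            "rho_b": rho_b,
            "p_b": p_b,
            "fdr_b": fdr_b,
            "program": assignment,
            "reportable": np.maximum(rho_a, rho_b) > min_rho_report,
            "n_cells": cells.size,
        }
    )


def program_shift_test(
    normalized: sp.spmatrix,
    gene_ids: list[str],
    programs: pd.DataFrame,
    cells_smoker: np.ndarray,
    cells_nonsmoker: np.ndarray,
    *,
    top_n: int = 25,
    directions: dict[str, str] = {"A_specific": "greater", "B_specific": "less"},
) -> pd.DataFrame:
    """One-sided rank-sum test of smoking shifts in program scores.

    Per cell, the score is the mean log-normalized expression over the
    program's top ``top_n`` genes by descending rho.  The alternative per
    program is declared in ``directions`` (default: the A program rises in
    smokers, the B program falls) — never inferred from the data.
    """
    if np.asarray(cells_smoker).size == 0 or np.asarray(cells_nonsmoker).size == 0:
        raise ValidationError("both smoking groups must be non-empty")
    lookup = {g: i for i, g in enumerate(gene_ids)}
    rows = []
    for program, alternative in directions.items():
        sub = programs[programs["program"] == program]
        if sub.empty:
            raise ValidationError(f"program {program!r} is empty")
        rho_col = "rho_a" if program == "A_specific" else "rho_b"
        genes = list(sub.sort_values(rho_col, ascending=False)["gene"].head(top_n))
        idx = [lookup[g] for g in genes]
        block = normalized[idx, :]
        if sp.issparse(block):
            block = block.toarray()
        score = np.asarray(block).mean(axis=0)
        s = score[np.asarray(cells_smoker)]
        ns = score[np.asarray(cells_nonsmoker)]
        p = wilcoxon_rank_sum(s, ns, alternative=alternative)
        rows.append((program, len(genes), alternative, p, s.mean(), ns.mean()))
    return pd.DataFrame(
        rows,
        columns=["program", "n_genes", "alternative", "p", "smoker_mean", "nonsmoker_mean"],
    )
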