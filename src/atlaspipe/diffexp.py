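"""Two-group differential expression with the pipeline's gates.

Smoker-versus-non-smoker contrasts use the Wilcoxon rank-sum test (exact by
enumeration for small tie-free groups, normal approximation with tie and
continuity corrections otherwise).  Population contrasts use a
likelihood-ratio test on logistic models of group membership with latent
covariates (smoking habit, donor identity), so expression must explain
group membership beyond the covariates.  Before testing, genes are gated on
|logFC| > 0.25 (natural log, +1-stabilized means of depth-normalized
counts) and detection in >10% of cells in at least one group; FDR is
Benjamini–Hochberg over tested genes only, significant at FDR < 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats

from .io_formats import ValidationError

__all__ = [
    "DEThresholds",
    "wilcoxon_rank_sum",
    "lr_test",
    "log_fold_change",
    "pct_expressed",
    "bh_fdr",
    "de_contrast",
    "donor_design",
]


@dataclass(frozen=True)
class DEThresholds:
    min_logfc: float = 0.25
    min_pct: float = 0.10
    alpha_fdr: float = 0.05

    def __post_init__(self) -> None:
        if self.min_logfc < 0:
            raise ValidationError("min_logfc must be >= 0")
        if not 0 < self.min_pct < 1:
            raise ValidationError("min_pct must be in (0, 1)")
        if not 0 < self.alpha_fdr < 1:
            raise ValidationError("alpha_fdr must be in (0, 1)")


def wilcoxon_rank_sum(
    a: np.ndarray, b: np.ndarray, alternative: str = "two_sided"
) -> float:
    """Rank-sum p-value for a shift between two samples.

    Exact null enumeration when the pooled sample is small (≤ 25
    observations) and tie-free; otherwise the normal approximation with tie
    and continuity corrections.  ``alternative='greater'`` tests whether
    ``a`` is shifted above ``b``.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValidationError("both samples must be non-empty")
    alt = {"two_sided": "two-sided", "greater": "greater", "less": "less"}[alternative]
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    if np.ptp(pooled) == 0:
        return 1.0  # complete tie: no evidence of a shift
    method = "exact" if (a.size + b.size <= 25 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative=alt, method=method, use_continuity=True)
    return float(min(res.pvalue, 1.0))


def _rank_sum_matrix(a: np.ndarray, b: np.ndarray, alternative: str) -> np.ndarray:
    """Column-wise asymptotic rank-sum p-values (cells × genes inputs)."""
    alt = {"two_sided": "two-sided", "greater": "greater", "less": "less"}[alternative]
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.mannwhitneyu(a, b, alternative=alt, method="asymptotic", axis=0)
    p = np.asarray(res.pvalue, dtype=float)
    # columns that are one single tied value carry no evidence
    ptp = np.ptp(np.vstack([a, b]), axis=0)
    p = np.where(ptp == 0, 1.0, p)
    return np.minimum(np.nan_to_num(p, nan=1.0), 1.0)


# ---------------------------------------------------------------------------
# logistic likelihood-ratio test


def _logistic_irls(
    X: np.ndarray, y: np.ndarray, ridge: float = 0.0, max_iter: int = 50, tol: float = 1e-10
) -> tuple[np.ndarray, float, bool]:
    """Newton/IRLS fit of a logistic model; returns (beta, loglik, converged).

    ``ridge`` adds an L2 penalty (excluding nothing) used as the fallback
    under perfect separation; the returned log-likelihood is unpenalized.
    """
    n, k = X.shape
    beta = np.zeros(k)
    ll_old = -np.inf
    converged = False
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        ll = float(np.sum(y * eta - np.log1p(np.exp(eta))))
        w = mu * (1.0 - mu)
        H = X.T @ (X * w[:, None]) + ridge * np.eye(k)
        g = X.T @ (y - mu) - ridge * beta
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, g, rcond=None)[0]
        beta = beta + step
        if abs(ll - ll_old) < tol:
            converged = True
            break
        ll_old = ll
    eta = np.clip(X @ beta, -30, 30)
    ll = float(np.sum(y * eta - np.log1p(np.exp(eta))))
    separated = np.abs(beta).max() > 25
    return beta, ll, converged and not separated


def lr_test(
    expr: np.ndarray,
    group: np.ndarray,
    covariates: np.ndarray | None = None,
) -> float:
    """Likelihood-ratio p-value that expression predicts group membership.

    Fits logistic models ``group ~ covariates`` and ``group ~ expr +
    covariates``; the statistic is twice the log-likelihood gain, referred
    to chi-square with 1 df.  Under perfect separation both models are
    refit with a small L2 ridge so the statistic stays finite.
    """
    expr = np.asarray(expr, dtype=float).ravel()
    group = np.asarray(group).ravel()
    classes = np.unique(group)
    if classes.size != 2:
        raise ValidationError("group must contain exactly two classes")
    y = (group == classes[1]).astype(float)
    n = y.size
    ones = np.ones((n, 1))
    if covariates is None:
        Z = ones
    else:
        C = np.atleast_2d(np.asarray(covariates, dtype=float))
        if C.shape[0] != n:
            C = C.T
        # drop constant columns; keep a full-rank design
        keep = [j for j in range(C.shape[1]) if np.ptp(C[:, j]) > 0]
        Z = np.hstack([ones, C[:, keep]]) if keep else ones
    X_full = np.hstack([Z, expr[:, None]])
    if np.ptp(expr) == 0:
        return 1.0

    _, ll0, ok0 = _logistic_irls(Z, y)
    _, ll1, ok1 = _logistic_irls(X_full, y)
    if not (ok0 and ok1):
        ridge = 1e-4 * n
        _, ll0, _ = _logistic_irls(Z, y, ridge=ridge, max_iter=100)
        _, ll1, _ = _logistic_irls(X_full, y, ridge=ridge, max_iter=100)
    lr = max(2.0 * (ll1 - ll0), 0.0)
    return float(stats.chi2.sf(lr, df=1)) if lr > 0 else 1.0


def donor_design(donors: np.ndarray) -> np.ndarray:
    """One-hot donor covariates with the first level dropped."""
    levels = pd.unique(np.asarray(donors))
    return np.column_stack([(donors == d).astype(float) for d in levels[1:]]) if len(levels) > 1 else np.zeros((len(donors), 0))


# ---------------------------------------------------------------------------
# effect sizes and adjustment


def _group_mean_counts(normalized: sp.spmatrix | np.ndarray, cols: np.ndarray) -> np.ndarray:
    """Per-gene mean depth-normalized count (expm1 of log1p values)."""
    sub = normalized[:, cols]
    if sp.issparse(sub):
        sub = sub.copy()
        sub.data = np.expm1(sub.data)
        return np.asarray(sub.mean(axis=1)).ravel()
    return np.expm1(np.asarray(sub)).mean(axis=1)


def log_fold_change(
    normalized: sp.spmatrix | np.ndarray,
    cells_a: np.ndarray,
    cells_b: np.ndarray,
) -> np.ndarray:
    """Natural-log fold-change of +1-stabilized group means, per gene.

    log(mean(expm1 x_a) + 1) − log(mean(expm1 x_b) + 1); antisymmetric under
    group exchange.
    """
    ma = _group_mean_counts(normalized, cells_a)
    mb = _group_mean_counts(normalized, cells_b)
    return np.log(ma + 1.0) - np.log(mb + 1.0)


def pct_expressed(counts: sp.spmatrix | np.ndarray, cols: np.ndarray) -> np.ndarray:
    """Per-gene fraction of cells with raw count > 0 in the column subset."""
    sub = counts[:, cols]
    det = (sub > 0).sum(axis=1)
    return np.asarray(det).ravel() / sub.shape[1]


def bh_fdr(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (order-preserving).

    Direct implementation of the step-up definition: sort, take
    p·m/rank, enforce monotonicity from the largest rank down, clip at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranks = np.arange(1, m + 1)
    stepped = (p[order] * m) / ranks
    adj_sorted = np.minimum(np.minimum.accumulate(stepped[::-1])[::-1], 1.0)
    adj = np.empty(m)
    adj[order] = adj_sorted
    return adj


def de_contrast(
    normalized: sp.spmatrix,
    counts: sp.spmatrix,
    gene_ids: list[str],
    cells_a: np.ndarray,
    cells_b: np.ndarray,
    t: DEThresholds = DEThresholds(),
    test: str = "wilcoxon",
    covariates: np.ndarray | None = None,
) -> pd.DataFrame:
    """Gated two-group DE over all genes; one row per gene.

    ``cells_a`` / ``cells_b`` are disjoint column index arrays.  Genes
    failing the logFC/detection gates carry ``tested=False`` and NaN
    p/FDR; FDR is adjusted over tested genes only.  For ``test='lr'``,
    ``covariates`` rows must align with ``concatenate([cells_a, cells_b])``.
    """
    cells_a = np.asarray(cells_a)
    cells_b = np.asarray(cells_b)
    if cells_a.size == 0 or cells_b.size == 0:
        raise ValidationError("both cell groups must be non-empty")
    if np.intersect1d(cells_a, cells_b).size:
        raise ValidationError("cell groups overlap")

    logfc = log_fold_change(normalized, cells_a, cells_b)
    pct_a = pct_expressed(counts, cells_a)
    pct_b = pct_expressed(counts, cells_b)
    tested = (np.abs(logfc) > t.min_logfc) & (np.maximum(pct_a, pct_b) > t.min_pct)

    p = np.full(len(gene_ids), np.nan)
    tested_idx = np.flatnonzero(tested)
    if tested_idx.size:
        sub = normalized[tested_idx, :]
        dense = sub.toarray() if sp.issparse(sub) else np.asarray(sub)
        A = dense[:, cells_a].T  # cells × genes
        B = dense[:, cells_b].T
        if test == "wilcoxon":
            p[tested_idx] = _rank_sum_matrix(A, B, "two_sided")
        elif test == "lr":
            group = np.concatenate([np.zeros(cells_a.size), np.ones(cells_b.size)])
            for j, gi in enumerate(tested_idx):
                expr = np.concatenate([A[:, j], B[:, j]])
                p[gi] = lr_test(expr, group, covariates)
        else:
            raise ValidationError(f"unknown test {test!r}")
    # multiplicity reflects the full screened universe (the gate is part of
    # the screen): untested genes enter the step-up at p = 1 but report no FDR
    fdr = np.full(len(gene_ids), np.nan)
    if tested_idx.size:
        fdr_all = bh_fdr(np.where(np.isnan(p), 1.0, p))
        fdr[tested_idx] = fdr_all[tested_idx]

    return pd.DataFrame(
        {
            "gene": gene_ids,
            "logfc": logfc,
            "pct_a": pct_a,
            "pct_b": pct_b,
            "p": p,
            "fdr": fdr,
            "tested": tested,
        }
    )
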