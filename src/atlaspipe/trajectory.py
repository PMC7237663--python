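"""Cluster-anchored lineage pseudotime, association testing, windowed
smoothing, and Gaussian-mixture endpoint isolation.

The lineage is the root-to-end path through a Euclidean minimum spanning
tree over population centroids in a reduced expression space (PCA over the
most dispersed genes).  Each member cell's pseudotime is the arc-length of
its orthogonal projection onto that piecewise-linear path.  Genes are
tested for pseudotime association by a likelihood-ratio comparison of a
natural cubic spline fit (df = 3) plus covariate against the
covariate-only model, BH-adjusted, flagged at q < 1e−10.  Expression is
smoothed with a triangular moving average over a 100-cell window.  The
terminal population is isolated by fitting a two-component 1-D Gaussian
mixture to pseudotime and keeping cells beyond two standard deviations
left of the endpoint (larger-mean) component.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial.distance import cdist

from .diffexp import bh_fdr
from .io_formats import ValidationError

__all__ = [
    "LineagePath",
    "MixtureFit",
    "pca_reduce",
    "build_lineage",
    "pseudotime_association",
    "smooth_expression",
    "fit_gmm2",
    "isolate_terminal",
]


# ---------------------------------------------------------------------------
# reduced space


def pca_reduce(
    normalized: sp.spmatrix,
    n_components: int = 10,
    n_top_genes: int = 1000,
    n_bins: int = 20,
) -> np.ndarray:
    """Deterministic PCA coordinates (cells × components) for lineage geometry.

    Informative genes are chosen by dispersion (variance over mean of
    depth-normalized counts) standardized within mean-quantile bins, which
    removes the mean–dispersion trend by ranking; the scaled log-normalized
    expression of the top genes is decomposed by full SVD with a fixed sign
    convention.
    """
    dense = normalized.toarray() if sp.issparse(normalized) else np.asarray(normalized)
    counts_scale = np.expm1(dense)
    mean = counts_scale.mean(axis=1)
    var = counts_scale.var(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        disp = np.where(mean > 0, var / np.maximum(mean, 1e-12), 0.0)
    expressed = mean > 0
    score = np.full(mean.size, -np.inf)
    # standardize dispersion within mean bins (rank-based detrending)
    order = np.argsort(mean[expressed])
    idx_expressed = np.flatnonzero(expressed)[order]
    bins = np.array_split(idx_expressed, n_bins)
    for b in bins:
        if b.size == 0:
            continue
        d = disp[b]
        sd = d.std()
        score[b] = (d - d.mean()) / sd if sd > 0 else 0.0
    n_top = min(n_top_genes, int(expressed.sum()))
    top = np.sort(np.argsort(score)[::-1][:n_top])

    X = np.log1p(counts_scale[top, :]).T  # cells × genes
    X = X - X.mean(axis=0)
    sd = X.std(axis=0)
    X = X / np.where(sd > 0, sd, 1.0)
    np.clip(X, -10, 10, out=X)
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    k = min(n_components, S.size)
    coords = U[:, :k] * S[:k]
    # fix component signs so the largest-magnitude loading is positive
    for j in range(k):
        i = np.argmax(np.abs(Vt[j]))
        if Vt[j, i] < 0:
            coords[:, j] = -coords[:, j]
    return coords


# ---------------------------------------------------------------------------
# lineage construction


@dataclass
class LineagePath:
    """Root-to-end population chain with per-cell projected pseudotime."""

    populations: list[str]
    centroids: np.ndarray  # path vertices in reduced space, in order
    pseudotime: np.ndarray  # per input cell; NaN off-lineage
    segment_lengths: np.ndarray

    @property
    def total_length(self) -> float:
        return float(self.segment_lengths.sum())


def _project_to_path(points: np.ndarray, vertices: np.ndarray) -> np.ndarray:
    """Arc-length coordinate of each point's nearest orthogonal projection."""
    seg_vec = np.diff(vertices, axis=0)
    seg_len = np.linalg.norm(seg_vec, axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    best_dist = np.full(points.shape[0], np.inf)
    best_arc = np.zeros(points.shape[0])
    for s in range(seg_vec.shape[0]):
        v = seg_vec[s]
        L2 = seg_len[s] ** 2
        if L2 == 0:
            t = np.zeros(points.shape[0])
        else:
            t = np.clip((points - vertices[s]) @ v / L2, 0.0, 1.0)
        proj = vertices[s] + t[:, None] * v
        d = np.linalg.norm(points - proj, axis=1)
        better = d < best_dist
        best_dist[better] = d[better]
        best_arc[better] = cum[s] + t[better] * seg_len[s]
    return best_arc


def build_lineage(
    reduced_coords: np.ndarray,
    labels: np.ndarray,
    root: str,
    end: str | None = None,
) -> LineagePath:
    """MST over population centroids; pseudotime by projection onto the
    root→end path (root→farthest-leaf when ``end`` is unset).

    Cells of populations off the path get NaN pseudotime.  Deterministic:
    no randomness anywhere in the construction.
    """
    labels = np.asarray(labels)
    coords = np.asarray(reduced_coords, dtype=float)
    pops = sorted(pd.unique(labels))
    if len(pops) < 2:
        raise ValidationError("need at least two populations")
    if root not in pops:
        raise ValidationError(f"root population {root!r} absent")
    if end is not None and end == root:
        raise ValidationError("root and end must differ")
    if end is not None and end not in pops:
        raise ValidationError(f"end population {end!r} absent")
    centroids = np.vstack([coords[labels == p].mean(axis=0) for p in pops])
    dist = cdist(centroids, centroids)
    mst = minimum_spanning_tree(dist).toarray()
    adj = (mst > 0) | (mst.T > 0)

    # path through the tree from root (BFS parents)
    iroot = pops.index(root)
    parent = {iroot: None}
    queue = [iroot]
    orderd = []
    while queue:
        u = queue.pop(0)
        orderd.append(u)
        for v in np.flatnonzero(adj[u]):
            if v not in parent:
                parent[v] = u
                queue.append(v)

    def path_to(i: int) -> list[int]:
        out = [i]
        while parent[out[-1]] is not None:
            out.append(parent[out[-1]])
        return out[::-1]

    if end is not None:
        iend = pops.index(end)
    else:
        # farthest vertex by tree path length
        def path_len(i: int) -> float:
            p = path_to(i)
            return sum(dist[p[j], p[j + 1]] for j in range(len(p) - 1))

        iend = max((i for i in range(len(pops)) if i != iroot), key=path_len)
    chain = path_to(iend)
    chain_pops = [pops[i] for i in chain]
    vertices = centroids[chain]
    seg_len = np.linalg.norm(np.diff(vertices, axis=0), axis=1)

    member = np.isin(labels, chain_pops)
    pseudotime = np.full(labels.size, np.nan)
    pseudotime[member] = _project_to_path(coords[member], vertices)

    med_root = np.nanmedian(pseudotime[labels == root])
    for p in chain_pops:
        if np.nanmedian(pseudotime[labels == p]) < med_root:
            raise ValidationError(
                "root cells are not at the start of the path; check root choice"
            )
    return LineagePath(chain_pops, vertices, pseudotime, seg_len)


# ---------------------------------------------------------------------------
# association with pseudotime


def _natural_spline_basis(x: np.ndarray, df: int = 3) -> np.ndarray:
    """Natural cubic spline basis (df columns, no intercept).

    Truncated-power construction with df + 1 knots at evenly spaced
    quantiles; linear beyond the boundary knots.
    """
    knots = np.quantile(x, np.linspace(0.05, 0.95, df + 1))
    knots = np.unique(knots)
    if knots.size < 3:
        raise ValidationError("pseudotime has too few distinct values for a spline")
    xi_K = knots[-1]
    xi_Km1 = knots[-2]

    def d(xi):
        return (np.maximum(x - xi, 0) ** 3 - np.maximum(x - xi_K, 0) ** 3) / (xi_K - xi)

    cols = [x]
    for xi in knots[:-2]:
        cols.append(d(xi) - d(xi_Km1))
    return np.column_stack(cols[:df])


def pseudotime_association(
    normalized: sp.spmatrix,
    gene_ids: list[str],
    pseudotime: np.ndarray,
    covariate: np.ndarray | None = None,
    q_threshold: float = 1e-10,
) -> pd.DataFrame:
    """Spline likelihood-ratio test of each gene against pseudotime.

    Compares a Gaussian linear model on a natural cubic spline basis of
    pseudotime (df = 3) plus covariate against the covariate-only model;
    the statistic n·log(RSS0/RSS1) is referred to chi-square with 3 df.
    Cells with NaN pseudotime are dropped.  Genes are flagged at
    q < ``q_threshold``.
    """
    pt = np.asarray(pseudotime, dtype=float)
    use = ~np.isnan(pt)
    if use.sum() < 20:
        raise ValidationError("need at least 20 cells with pseudotime")
    pt = pt[use]
    if np.ptp(pt) == 0:
        raise ValidationError("pseudotime is constant")
    sub = normalized[:, np.flatnonzero(use)]
    Y = (sub.toarray() if sp.issparse(sub) else np.asarray(sub)).T  # cells × genes
    n = Y.shape[0]
    ones = np.ones((n, 1))
    if covariate is None:
        X0 = ones
    else:
        cov = np.asarray(covariate, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        if cov.shape[0] == use.size and use.size != n:
            cov = cov[use]  # covariate given for all cells, incl. NaN-pt ones
        if cov.shape[0] != n:
            raise ValidationError("covariate length does not match cells")
        cov = cov[:, [j for j in range(cov.shape[1]) if np.ptp(cov[:, j]) > 0]]
        X0 = np.hstack([ones, cov]) if cov.shape[1] else ones
    spline = _natural_spline_basis(pt, df=3)
    X1 = np.hstack([X0, spline])

    def rss(X: np.ndarray) -> np.ndarray:
        Q, _ = np.linalg.qr(X)
        resid = Y - Q @ (Q.T @ Y)
        return (resid**2).sum(axis=0)

    rss0 = rss(X0)
    rss1 = rss(X1)
    with np.errstate(divide="ignore", invalid="ignore"):
        lr = n * np.log(np.maximum(rss0, 1e-300) / np.maximum(rss1, 1e-300))
    lr = np.where((rss0 == 0) & (rss1 == 0), 0.0, np.maximum(lr, 0.0))
    df_test = X1.shape[1] - X0.shape[1]
    p = stats.chi2.sf(lr, df=df_test)
    q = bh_fdr(p)
    return pd.DataFrame(
        {"gene": gene_ids, "statistic": lr, "p": p, "q": q, "flagged": q < q_threshold}
    )


# ---------------------------------------------------------------------------
# smoothing


def smooth_expression(
    values: np.ndarray, pseudotime: np.ndarray, window: int = 100
) -> np.ndarray:
    """Triangular moving average over cells sorted by pseudotime.

    The window is truncated symmetrically at the ends, so the output is
    always a convex combination of inputs and has the same length.
    Returned in pseudotime-sorted order.
    """
    values = np.asarray(values, dtype=float)
    pt = np.asarray(pseudotime, dtype=float)
    if window < 3:
        raise ValidationError("window must be >= 3")
    n = values.size
    if n < window:
        raise ValidationError(f"need at least {window} cells, got {n}")
    order = np.argsort(pt, kind="stable")
    v = values[order]
    half = (window - 1) // 2
    out = np.empty(n)
    for i in range(n):
        h = min(half, i, n - 1 - i)
        offs = np.arange(-h, h + 1)
        w = (h + 1) - np.abs(offs)
        out[i] = np.average(v[i + offs], weights=w)
    return out


# ---------------------------------------------------------------------------
# two-component Gaussian mixture


@dataclass
class MixtureFit:
    """EM fit of a two-component 1-D Gaussian mixture (mu1 ≤ mu2)."""

    weights: tuple[float, float]
    means: tuple[float, float]
    sds: tuple[float, float]
    log_likelihood: float
    iterations: int
    converged: bool
    ll_trajectory: list[float] = field(default_factory=list)

    @property
    def separated(self) -> bool:
        """Component-separation diagnostic: means ≥ 2 max-sd apart."""
        return abs(self.means[1] - self.means[0]) >= 2.0 * max(self.sds)


def fit_gmm2(
    values: np.ndarray,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-8,
) -> MixtureFit:
    """EM for a two-component 1-D Gaussian mixture.

    Initialization is deterministic (means at the 25th/75th percentiles,
    both sds at the pooled sd, equal weights); ``seed`` is accepted for
    interface symmetry but the fit itself draws no random numbers.  Sds
    are floored at 1e−6 of the data range; components are relabeled so
    mu1 ≤ mu2; convergence is declared when the log-likelihood gain drops
    below ``tol``.  The log-likelihood is non-decreasing across
    iterations (an EM guarantee the fit records and asserts).
    """
    x = np.asarray(values, dtype=float).ravel()
    if np.unique(x).size < 10:
        raise ValidationError("need at least 10 distinct values")
    floor = 1e-6 * np.ptp(x)
    mu = np.percentile(x, [25.0, 75.0]).astype(float)
    sd = np.array([x.std(), x.std()])
    w = np.array([0.5, 0.5])
    ll_old = -np.inf
    traj: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # E step
        log_pdf = stats.norm.logpdf(x[:, None], mu[None, :], sd[None, :]) + np.log(w)[None, :]
        m = log_pdf.max(axis=1, keepdims=True)
        lse = m.ravel() + np.log(np.exp(log_pdf - m).sum(axis=1))
        ll = float(lse.sum())
        if traj and ll < traj[-1] - 1e-9:
            raise AssertionError("EM log-likelihood decreased")
        traj.append(ll)
        if ll - ll_old < tol:
            converged = True
            break
        ll_old = ll
        resp = np.exp(log_pdf - lse[:, None])
        # M step
        nk = resp.sum(axis=0)
        w = nk / x.size
        mu = (resp * x[:, None]).sum(axis=0) / nk
        var = (resp * (x[:, None] - mu[None, :]) ** 2).sum(axis=0) / nk
        sd = np.maximum(np.sqrt(var), floor)
    if mu[0] > mu[1]:
        mu, sd, w = mu[::-1], sd[::-1], w[::-1]
    return MixtureFit(
        weights=(float(w[0]), float(w[1])),
        means=(float(mu[0]), float(mu[1])),
        sds=(float(sd[0]), float(sd[1])),
        log_likelihood=traj[-1],
        iterations=it,
        converged=converged,
        ll_trajectory=traj,
    )


def isolate_terminal(pseudotime: np.ndarray, fit: MixtureFit) -> np.ndarray:
    """Mask of cells beyond two sds left of the endpoint component.

    The endpoint is the larger-mean component; cells with pseudotime >
    mu2 − 2·sd2 are selected.  Requires a converged, separated fit.
    """
    if not fit.converged:
        raise ValidationError("mixture fit did not converge; refusing endpoint isolation")
    if not fit.separated:
        raise ValidationError(
            "mixture components are not separated (|mu2-mu1| < 2·max sd); "
            "endpoint isolation would be arbitrary"
        )
    pt = np.asarray(pseudotime, dtype=float)
    return pt > fit.means[1] - 2.0 * fit.sds[1]
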