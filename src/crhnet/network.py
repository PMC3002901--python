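"""Unsupervised structure on the candidate genes: PCA and a shrinkage GGM.

:func:`pca_biplot` decomposes the row-centered genes x samples ratio matrix
so genes (scores) and samples (loadings) can be displayed jointly.

The graphical-Gaussian-model route estimates partial correlations from a
James-Stein-type shrinkage of the (optionally time-weighted) correlation
matrix — the small-n, moderate-p regime of a 30-sample time course makes the
unregularized estimate unusable.  Edge significance comes from the null
density of partial correlations, f(r) proportional to (1 - r^2)^((kappa-3)/2),
with the effective degrees of freedom kappa fitted by maximum likelihood to
the observed edge ensemble under the assumption that most edges are null.
Edges are kept when |pcor| exceeds a threshold *and* the p-value is below a
cap; unconnected nodes stay in the node set.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

logger = logging.getLogger(__name__)


@dataclass
class PcaResult:
    """Scores (genes), loadings (samples) and explained variance."""

    scores: pd.DataFrame
    loadings: pd.DataFrame
    explained_variance_ratio: np.ndarray

    def reconstruct(self) -> np.ndarray:
        """Spectral reconstruction of the row-centered matrix."""
        return self.scores.to_numpy() @ self.loadings.to_numpy().T


@dataclass
class GgmNetwork:
    """Thresholded partial-correlation network."""

    nodes: list
    edges: pd.DataFrame           # gene_i, gene_j (i < j), pcor, p, sign
    pcor_min: float
    p_max: float

    @property
    def unconnected(self) -> list:
        touched = set(self.edges["gene_i"]) | set(self.edges["gene_j"])
        return [n for n in self.nodes if n not in touched]

    def edge_set(self) -> set:
        return {
            frozenset((r.gene_i, r.gene_j)) for r in self.edges.itertuples()
        }

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for r in self.edges.itertuples():
            g.add_edge(r.gene_i, r.gene_j, pcor=r.pcor, p=r.p, sign=r.sign)
        return g


def pca_biplot(matrix: pd.DataFrame) -> PcaResult:
    """PCA of the row-centered genes x samples matrix, biplot layout.

    Scores = U S carry the genes, loadings = V carry the samples, so
    ``scores @ loadings.T`` reproduces the centered matrix exactly.
    """
    if matrix.shape[0] < 2 or matrix.shape[1] < 2:
        raise ValueError("need at least 2 genes and 2 samples")
    X = matrix.to_numpy(dtype=float)
    Xc = X - X.mean(axis=1, keepdims=True)
    if not np.any(Xc):
        raise ValueError("matrix has zero variance after row centering")
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    evr = s**2 / np.sum(s**2)
    pcs = [f"PC{i + 1}" for i in range(s.size)]
    return PcaResult(
        scores=pd.DataFrame(U * s, index=matrix.index, columns=pcs),
        loadings=pd.DataFrame(Vt.T, index=matrix.columns, columns=pcs),
        explained_variance_ratio=evr,
    )


def dynamic_weights(time_points) -> np.ndarray:
    """Trapezoid-rule sample weights for unequally spaced time series.

    Each distinct time point receives a weight proportional to the interval
    it spans on the time grid (half the gap to each neighbour); replicates
    at a time point split that weight equally.  Weights sum to 1.  This is
    the time-aware ("dynamic") weighting used before the correlation
    estimate; with a single time point it degenerates to uniform weights.
    """
    t = np.asarray(time_points, dtype=float)
    grid = np.unique(t)
    if grid.size < 2:
        warnings.warn("single time point: uniform weights", stacklevel=2)
        return np.full(t.size, 1.0 / t.size)
    gw = np.empty(grid.size)
    gw[0] = (grid[1] - grid[0]) / 2.0
    gw[-1] = (grid[-1] - grid[-2]) / 2.0
    if grid.size > 2:
        gw[1:-1] = (grid[2:] - grid[:-2]) / 2.0
    w = np.empty(t.size)
    for g, weight in zip(grid, gw):
        idx = t == g
        w[idx] = weight / idx.sum()
    return w / w.sum()


def _weighted_correlation(X: np.ndarray, w: np.ndarray):
    """Weighted Pearson correlation and per-entry variance estimates.

    Rows of X are variables.  With equal weights this reduces to the usual
    unbiased-variance Pearson estimate and the standard small-sample
    variance formula var(r_ij) = n / (n-1)^3 * sum_k (p_k - p_bar)^2 over
    the products p_k of standardized values.
    """
    w = w / w.sum()
    h1 = 1.0 / (1.0 - np.sum(w**2))
    mean = X @ w
    Xc = X - mean[:, None]
    var = h1 * (Xc**2 @ w)
    sd = np.sqrt(var)
    sd[sd == 0] = np.inf            # constant rows correlate with nothing
    Xs = Xc / sd[:, None]
    R = h1 * (Xs * w) @ Xs.T
    np.fill_diagonal(R, 1.0)
    R = np.clip(R, -1.0, 1.0)
    # variance of each r_ij from the spread of the standardized products
    prods = Xs[:, None, :] * Xs[None, :, :]          # (p, p, n)
    pbar = prods @ w
    var_r = h1**3 * ((prods - pbar[:, :, None]) ** 2 @ (w**2))
    return R, var_r


def shrinkage_pcor(
    matrix: pd.DataFrame,
    weights: np.ndarray | None = None,
    shrinkage: float | None = None,
) -> pd.DataFrame:
    """Partial correlations from a shrinkage correlation estimate.

    The correlation matrix is shrunk toward the identity with the
    analytically estimated intensity
    ``lambda* = sum var(r_ij) / sum r_ij^2`` (off-diagonal sums, clipped to
    [0, 1]); partial correlations follow from the inverse:
    r_p(i,j) = -Omega_ij / sqrt(Omega_ii Omega_jj).  Genes are mean-centered
    (and scaled) per row as part of the correlation step.  ``shrinkage``
    overrides the estimated intensity.

    The estimated intensity is stored in ``result.attrs['shrinkage']``.
    """
    if matrix.shape[0] < 2:
        raise ValueError("need at least 2 genes for partial correlations")
    X = matrix.to_numpy(dtype=float)
    n = X.shape[1]
    w = np.full(n, 1.0 / n) if weights is None else np.asarray(weights, float)
    R, var_r = _weighted_correlation(X, w)
    off = ~np.eye(R.shape[0], dtype=bool)
    denom = np.sum(R[off] ** 2)
    if shrinkage is not None:
        lam = shrinkage
    elif denom == 0:
        lam = 1.0
    else:
        lam = float(np.clip(np.sum(var_r[off]) / denom, 0.0, 1.0))
    R_shrunk = (1.0 - lam) * R
    np.fill_diagonal(R_shrunk, 1.0)
    omega = np.linalg.inv(R_shrunk)
    d = np.sqrt(np.diag(omega))
    pcor = -omega / np.outer(d, d)
    np.fill_diagonal(pcor, 1.0)
    out = pd.DataFrame(pcor, index=matrix.index, columns=matrix.index)
    out.attrs["shrinkage"] = lam
    logger.info("shrinkage intensity lambda* = %.4f", lam)
    return out


def _kappa_loglik(kappa: float, r: np.ndarray) -> float:
    return float(
        np.sum((kappa - 3.0) / 2.0 * np.log1p(-(r**2)))
        - r.size * special.betaln(0.5, (kappa - 1.0) / 2.0)
    )


def fit_kappa(pcors: np.ndarray, method: str = "median") -> float:
    """Effective degrees of freedom of the null pcor density, from the
    observed edge ensemble under the assumption that most edges are null.

    Under the null, r^2 is approximately chi2_1 / kappa for large kappa, so
    the default robust moment fit matches the median:
    kappa = median(chi2_1) / median(r^2) + 2.  The median is insensitive to
    the minority of true (alternative) edges, which would otherwise inflate
    the apparent null spread and cost power.  ``method='ml'`` instead
    maximizes the full likelihood of f(r) over all edges.
    """
    r = np.clip(np.asarray(pcors, dtype=float), -0.999999, 0.999999)
    if method == "ml":
        res = optimize.minimize_scalar(
            lambda k: -_kappa_loglik(k, r), bounds=(2.001, 1e5),
            method="bounded",
        )
        return float(res.x)
    med = np.median(r**2)
    if med <= 0:
        return 1e5                      # degenerate all-zero ensemble
    return float(min(stats.chi2.ppf(0.5, 1) / med + 2.0, 1e5))


def edge_significance(
    pcor: pd.DataFrame,
    n_samples: int | None = None,
    kappa: float | None = None,
) -> pd.DataFrame:
    """Two-sided p-value per edge under the null partial-correlation density.

    Under the null, r^2 follows Beta(1/2, (kappa-1)/2), so the two-sided
    tail probability is the upper Beta tail of r^2.  The null density
    describes *unshrunk* partial correlations, while the shrinkage estimate
    attenuates every entry by roughly (1 - lambda); when the input carries
    its shrinkage intensity (``attrs['shrinkage']`` from
    :func:`shrinkage_pcor`) the statistic is de-attenuated by that factor
    before the tail probability is taken.  A fully shrunk estimate
    (lambda = 1, all partial correlations zero) carries no evidence and
    yields p = 1 everywhere.

    ``kappa`` is normally fitted from the edge ensemble; with fewer than 5
    edges the fit is unstable and the theoretical value n - (p - 2) is used
    instead.
    """
    P = pcor.to_numpy(dtype=float)
    p_genes = P.shape[0]
    iu = np.triu_indices(p_genes, k=1)
    lam = pcor.attrs.get("shrinkage", 0.0)
    if lam >= 1.0:
        out = pd.DataFrame(
            np.ones_like(P), index=pcor.index, columns=pcor.columns
        )
        out.attrs["kappa"] = np.nan
        return out
    r = np.clip(P[iu] / (1.0 - lam), -0.999999, 0.999999)
    if kappa is None:
        if r.size < 5:
            if n_samples is None:
                raise ValueError(
                    "fewer than 5 edges: supply n_samples for the kappa "
                    "fallback"
                )
            kappa = float(n_samples - (p_genes - 2))
            warnings.warn(
                f"<5 edges; falling back to kappa = {kappa}", stacklevel=2
            )
        else:
            kappa = fit_kappa(r)
            logger.info("fitted null density kappa = %.2f", kappa)
    pv = np.ones_like(P)
    pv[iu] = stats.beta.sf(r**2, 0.5, (kappa - 1.0) / 2.0)
    pv.T[iu] = pv[iu]
    out = pd.DataFrame(pv, index=pcor.index, columns=pcor.columns)
    out.attrs["kappa"] = kappa
    return out


def build_network(
    pcor: pd.DataFrame,
    pvals: pd.DataFrame,
    pcor_min: float = 0.35,
    p_max: float = 0.05,
) -> GgmNetwork:
    """Conjunctive edge filter: |pcor| > pcor_min and p < p_max.

    All genes stay in the node set even when unconnected.
    """
    if pcor.shape != pvals.shape:
        raise ValueError("pcor and p-value matrices must match")
    nodes = list(pcor.index)
    P = pcor.to_numpy()
    pv = pvals.to_numpy()
    rows = []
    for i in range(len(nodes)):
        for j in range(i + 1, len(nodes)):
            if abs(P[i, j]) > pcor_min and pv[i, j] < p_max:
                rows.append(
                    (nodes[i], nodes[j], P[i, j], pv[i, j],
                     "+" if P[i, j] > 0 else "-")
                )
    edges = pd.DataFrame(
        rows, columns=["gene_i", "gene_j", "pcor", "p", "sign"]
    )
    return GgmNetwork(nodes, edges, pcor_min, p_max)


def infer_network(
    matrix: pd.DataFrame,
    time_points=None,
    pcor_min: float = 0.35,
    p_max: float = 0.05,
    dynamic: bool = True,
) -> GgmNetwork:
    """Full GGM route: weights -> shrinkage pcor -> edge test -> filter."""
    weights = None
    if dynamic and time_points is not None:
        weights = dynamic_weights(time_points)
    pcor = shrinkage_pcor(matrix, weights=weights)
    pvals = edge_significance(pcor, n_samples=matrix.shape[1])
    return build_network(pcor, pvals, pcor_min, p_max)
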