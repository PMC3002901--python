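"""Comparison selectors: greedy Wilks-Lambda forward selection and random
forest Gini-importance ranking.

The greedy selector performs classical stepwise-forward discriminant
analysis: starting from the gene with the smallest overall F-statistic
p-value, it repeatedly adds the gene minimizing the partial Wilks-Lambda
p-value while that p-value stays below a significance level (niveau).  Run
inside a leave-one-out wrapper it yields a gene-frequency ranking over the
30 training sets and an LOOCV error estimate.

The random-forest selector delegates tree construction to scikit-learn and
ranks genes by mean decrease in Gini impurity, with the out-of-bag error as
its accuracy estimate; permutation importance is available behind a flag.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance

from .containers import RatioMatrix
from .discriminant import fit_mlhd
from .ga import SelectionRun

logger = logging.getLogger(__name__)


@dataclass
class WilksResult:
    """Wilks-Lambda statistic for one candidate step."""

    lam: float              # Lambda = det(W) / det(T), in (0, 1]
    partial_lam: float      # Lambda_{p+1} / Lambda_p for the added gene
    f_stat: float
    p_value: float
    df: tuple               # (df1, df2) of the partial F


@dataclass
class RfParams:
    """Random-forest settings (defaults follow standard usage: 500 trees,
    mtry = all genes, terminal node size 1)."""

    n_trees: int = 500
    m_try: int | None = None        # None -> all genes
    node_size: int = 1
    importance: str = "gini"        # or "permutation"
    seed: int = 0

    def __post_init__(self):
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.importance not in ("gini", "permutation"):
            raise ValueError("importance must be 'gini' or 'permutation'")


def _scatter_grams(X: np.ndarray, y: np.ndarray):
    """Within-group (W) and total (T) Gram matrices over all genes."""
    classes, y_idx = np.unique(y, return_inverse=True)
    counts = np.bincount(y_idx).astype(float)
    sums = np.zeros((classes.size, X.shape[1]))
    np.add.at(sums, y_idx, X)
    means = sums / counts[:, None]
    D = X - means[y_idx]
    C = X - X.mean(axis=0)
    return D.T @ D, C.T @ C, classes.size


def wilks_lambda(X: np.ndarray, y: np.ndarray) -> WilksResult:
    """Wilks Lambda of a gene subset with its overall/partial F test.

    For a k-variable model entered in one step (against the empty model),
    the partial Lambda equals Lambda itself and the F statistic with
    df (G-1, n-G-k+1) reduces, at k = 1, to the one-way ANOVA F.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == X.ndim == 1:
        X = X.T
    n, k = X.shape
    W, T, G = _scatter_grams(X, np.asarray(y))
    if k >= n - G:
        raise ValueError(
            f"subset size {k} leaves no residual df (n={n}, groups={G})"
        )
    lam = _lambda_from_grams(W, T)
    return _partial_result(lam, 1.0, n, G, p_before=k - 1)


def _lambda_from_grams(W: np.ndarray, T: np.ndarray) -> float:
    sw, ldw = np.linalg.slogdet(W)
    st, ldt = np.linalg.slogdet(T)
    if sw <= 0 or st <= 0:
        return 0.0
    return float(np.exp(ldw - ldt))


def _partial_result(
    lam_new: float, lam_old: float, n: int, G: int, p_before: int
) -> WilksResult:
    """Partial-Lambda F test for adding one variable to a p-variable model.

    F = ((n - G - p) / (G - 1)) * (1 - L) / L with L = Lambda_{p+1}/Lambda_p,
    referred to F(G - 1, n - G - p).
    """
    df1, df2 = G - 1, n - G - p_before
    if df2 < 1:
        raise ValueError("insufficient residual df for the partial F test")
    partial = lam_new / lam_old if lam_old > 0 else 1.0
    partial = min(max(partial, 1e-300), 1.0)
    f = (df2 / df1) * (1.0 - partial) / partial
    p = float(stats.f.sf(f, df1, df2))
    return WilksResult(lam_new, partial, float(f), p, (df1, df2))


def greedy_forward(
    X: np.ndarray,
    y: np.ndarray,
    alpha: float = 0.001,
    max_genes: int = 10,
) -> tuple[list, list]:
    """Stepwise-forward selection on the partial Wilks-Lambda criterion.

    Adds, at each step, the gene minimizing the partial-Lambda p-value, as
    long as that p-value is below ``alpha`` and residual df remain; stops
    otherwise or at the ``max_genes`` safety cap.  Returns (selected column
    indices in insertion order, acceptance p-values).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n, n_genes = X.shape
    W, T, G = _scatter_grams(X, y)
    selected: list = []
    pvals: list = []
    lam_old = 1.0
    while len(selected) < min(max_genes, n - G - 1):
        p_before = len(selected)
        cand = np.setdiff1d(np.arange(n_genes), selected)
        idx_new = np.array([selected + [j] for j in cand])
        w_sub = W[idx_new[:, :, None], idx_new[:, None, :]]
        t_sub = T[idx_new[:, :, None], idx_new[:, None, :]]
        sw, ldw = np.linalg.slogdet(w_sub)
        st, ldt = np.linalg.slogdet(t_sub)
        # a candidate collinear with the current model makes W singular:
        # it adds no discriminative information and is ineligible
        eligible = (sw > 0) & (st > 0)
        with np.errstate(over="ignore"):
            lam = np.where(eligible, np.exp(ldw - ldt), 1.0)
        if lam_old > 0:
            partial = np.clip(lam / lam_old, 1e-300, 1.0)
        else:
            partial = np.ones_like(lam)
        df1, df2 = G - 1, n - G - p_before
        f = (df2 / df1) * (1.0 - partial) / partial
        p = np.where(eligible, stats.f.sf(f, df1, df2), 1.0)
        best = int(np.lexsort((cand, p))[0])
        if not np.isfinite(p[best]) or p[best] >= alpha:
            break
        selected.append(int(cand[best]))
        pvals.append(float(p[best]))
        lam_old = float(lam[best])
    if not selected:
        warnings.warn("greedy selection accepted no gene at step 1",
                      stacklevel=2)
    if len(selected) == max_genes:
        logger.info("greedy selection hit the max_genes cap (%d)", max_genes)
    return selected, pvals


def greedy_loocv(
    pool: RatioMatrix,
    alpha: float = 0.001,
    max_genes: int = 10,
) -> SelectionRun:
    """Greedy Wilks-Lambda selection inside a leave-one-out wrapper.

    For each of the n folds the greedy selector runs on the n-1 training
    samples, an LDA model is fit on the selected genes and the held-out
    sample predicted.  Genes are ranked by the number of training sets that
    picked them; the overall misclassification fraction is the LOOCV error.
    Folds with an empty selection fall back to the majority training class
    and are counted in ``extras['empty_folds']``.
    """
    X = pool.matrix().T
    y = pool.time
    gene_ids = pool.gene_ids
    n = X.shape[0]
    counts: dict = {}
    correct = 0
    empty_folds = 0
    fold_sizes = []
    for i in range(n):
        tr = np.delete(np.arange(n), i)
        sel, _p = greedy_forward(X[tr], y[tr], alpha, max_genes)
        fold_sizes.append(len(sel))
        if not sel:
            empty_folds += 1
            values, cnt = np.unique(y[tr], return_counts=True)
            pred = values[np.argmax(cnt)]
        else:
            model = fit_mlhd(X[tr][:, sel], y[tr])
            pred = model.predict(X[i, sel])[0]
        correct += pred == y[i]
        for j in sel:
            counts[gene_ids[j]] = counts.get(gene_ids[j], 0) + 1
    error = 1.0 - correct / n
    table = pd.DataFrame(
        sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])),
        columns=["gene", "frequency"],
    ).set_index("gene")
    table["rank"] = np.arange(1, len(table) + 1)
    return SelectionRun(
        method="greedy_wilks",
        params={"alpha": alpha, "max_genes": max_genes},
        solutions=[],
        ranking=table,
        n_attempts=n,
        seed=0,
        error=float(error),
        extras={"empty_folds": empty_folds, "fold_sizes": fold_sizes},
    )


def rf_rank(pool: RatioMatrix, params: RfParams = None) -> SelectionRun:
    """Random-forest gene ranking by mean decrease in Gini impurity.

    mtry defaults to all genes and terminal nodes are grown to size
    ``node_size``; the out-of-bag error is the accuracy estimate.  With
    ``importance='permutation'`` the ranking uses permutation importance
    instead of impurity decrease.
    """
    params = params or RfParams()
    X = pool.matrix().T
    y = pool.time
    if np.unique(y).size < 2:
        raise ValueError("random forest needs at least 2 classes")
    if X.shape[1] < 2:
        raise ValueError("random forest ranking needs at least 2 genes")
    m_try = params.m_try or X.shape[1]
    forest = RandomForestClassifier(
        n_estimators=params.n_trees,
        max_features=m_try,
        min_samples_leaf=params.node_size,
        oob_score=True,
        random_state=params.seed,
        n_jobs=1,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # few-tree OOB coverage warnings
        forest.fit(X, y)
    if params.importance == "gini":
        imp = forest.feature_importances_
    else:
        imp = permutation_importance(
            forest, X, y, n_repeats=10, random_state=params.seed
        ).importances_mean
    # ties (e.g. never-used genes at importance 0) break by gene id
    table = pd.DataFrame(
        {"importance": imp}, index=pool.gene_ids
    ).sort_index().sort_values("importance", ascending=False, kind="stable")
    table["rank"] = np.arange(1, len(table) + 1)
    oob_error = 1.0 - float(forest.oob_score_)
    return SelectionRun(
        method=f"random_forest_{params.importance}",
        params=params,
        solutions=[],
        ranking=table,
        n_attempts=params.n_trees,
        seed=params.seed,
        error=oob_error,
    )
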