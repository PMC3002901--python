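"""Univariate prefiltering statistics for the time-course ratio matrix.

Two fixed-effects two-way ANOVA passes drive the prefilter: a model *with*
the time x dye interaction identifies genes whose expression ratio depends on
the dye orientation over time (a labeling artifact; these are excluded), and
a model *without* interaction then preselects genes significantly regulated
over time.  Benjamini-Hochberg FDR is reported alongside each raw-p cut, and
Levene (trimmed) and Shapiro-Wilk tests check the ANOVA assumptions of
variance homogeneity and log-normality.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import RatioMatrix


@dataclass
class PrefilterResult:
    """Outcome of the two-stage univariate prefilter."""

    excluded: pd.DataFrame      # interaction-significant genes (p, q)
    preselected: pd.DataFrame   # time-significant genes among the remainder
    interaction_alpha: float
    time_alpha: float
    achieved_fdr_interaction: float
    achieved_fdr_time: float
    anova_interaction: pd.DataFrame
    anova_time: pd.DataFrame

    @property
    def preselected_ids(self) -> list:
        return list(self.preselected.index)


def _check_balanced(time: np.ndarray, dye: np.ndarray):
    cells = pd.crosstab(pd.Series(time), pd.Series(dye))
    counts = cells.to_numpy()
    if counts.min() < 1 or counts.min() != counts.max():
        raise ValueError(
            "two-way ANOVA requires a balanced time x dye design; observed "
            f"cell counts:\n{cells}"
        )
    return counts[0, 0]


def two_way_anova(
    values: np.ndarray,
    time: np.ndarray,
    dye: np.ndarray,
    with_interaction: bool = True,
) -> pd.DataFrame:
    """Per-gene fixed-effects two-way ANOVA on a balanced design.

    ``values`` is (genes x samples).  With balance, Type I/II/III sums of
    squares coincide and the classical cell-mean decomposition applies:
    SS_time, SS_dye and (optionally) SS_interaction are taken against the
    residual mean square with df (T-1), (J-1), (T-1)(J-1) and
    n - TJ (with interaction) or n - T - J + 1 (without).

    Returns a DataFrame with F and p per fitted effect plus a ``degenerate``
    flag for genes with zero residual variance (their p-values are NaN,
    never silently 0).
    """
    values = np.atleast_2d(np.asarray(values, dtype=float))
    time = np.asarray(time)
    dye = np.asarray(dye)
    n = values.shape[1]
    _check_balanced(time, dye)
    t_levels, t_idx = np.unique(time, return_inverse=True)
    d_levels, d_idx = np.unique(dye, return_inverse=True)
    T, J = t_levels.size, d_levels.size

    grand = values.mean(axis=1, keepdims=True)

    def _group_means(idx, k):
        sums = np.zeros((values.shape[0], k))
        counts = np.bincount(idx, minlength=k).astype(float)
        np.add.at(sums.T, idx, values.T)
        return sums / counts, counts

    tm, tc = _group_means(t_idx, T)
    dm, dc = _group_means(d_idx, J)
    cell_idx = t_idx * J + d_idx
    cm, cc = _group_means(cell_idx, T * J)

    ss_total = ((values - grand) ** 2).sum(axis=1)
    ss_time = (tc * (tm - grand) ** 2).sum(axis=1)
    ss_dye = (dc * (dm - grand) ** 2).sum(axis=1)
    ss_cells = (cc * (cm - grand) ** 2).sum(axis=1)
    ss_int = ss_cells - ss_time - ss_dye

    df_time, df_dye, df_int = T - 1, J - 1, (T - 1) * (J - 1)
    if with_interaction:
        ss_res = ss_total - ss_cells
        df_res = n - T * J
    else:
        ss_res = ss_total - ss_time - ss_dye
        df_res = n - T - J + 1
    if df_res <= 0:
        raise ValueError("no residual degrees of freedom")

    ms_res = ss_res / df_res
    degenerate = ms_res <= 1e-12 * np.maximum(ss_total, 1e-300)

    def _f_p(ss, df):
        with np.errstate(divide="ignore", invalid="ignore"):
            f = (ss / df) / ms_res
        f = np.where(degenerate, np.nan, f)
        p = stats.f.sf(f, df, df_res)
        return f, np.where(degenerate, np.nan, p)

    out = {}
    out["F_time"], out["p_time"] = _f_p(ss_time, df_time)
    out["F_dye"], out["p_dye"] = _f_p(ss_dye, df_dye)
    if with_interaction:
        out["F_interaction"], out["p_interaction"] = _f_p(ss_int, df_int)
    table = pd.DataFrame(out)
    table["degenerate"] = degenerate
    table.attrs["df"] = {
        "time": df_time, "dye": df_dye,
        "interaction": df_int if with_interaction else None,
        "residual": df_res,
    }
    table.attrs["ss"] = {
        "total": ss_total, "time": ss_time, "dye": ss_dye,
        "interaction": ss_int if with_interaction else None,
        "residual": ss_res,
    }
    return table


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    NaN entries propagate and are excluded from the number of tests m.
    """
    p = np.asarray(pvals, dtype=float)
    q = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        if (p[ok] < 0).any() or (p[ok] > 1).any():
            raise ValueError("p-values must lie in [0, 1]")
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


def levene_trimmed(values, groups, trim: float = 0.25) -> tuple[float, float]:
    """Levene/Brown-Forsythe test on deviations from the trimmed group mean.

    With ``trim = 0`` this reduces to the classical Levene test on group
    means.  Returns (statistic, p).  A completely spread-free input (all
    deviations zero) yields statistic 0 and p = 1 rather than a division
    error.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    levels = np.unique(groups)
    if levels.size < 2:
        raise ValueError("need at least 2 groups")
    by_group = [values[groups == g] for g in levels]
    if any(len(g) < 3 for g in by_group):
        raise ValueError("each group needs at least 3 values")
    center = "mean" if trim == 0 else "trimmed"
    if all(np.ptp(g) == 0 for g in by_group):
        return 0.0, 1.0
    stat, p = stats.levene(
        *by_group, center=center, proportiontocut=trim
    )
    return float(stat), float(p)


def shapiro_per_gene(matrix: RatioMatrix) -> pd.DataFrame:
    """Shapiro-Wilk normality test per gene over its sample ratios.

    Constant genes are flagged (p NaN) and excluded from the summary counts
    stored in ``DataFrame.attrs['n_below_001']``.
    """
    values = matrix.matrix()
    ps = np.full(values.shape[0], np.nan)
    ws = np.full(values.shape[0], np.nan)
    flags = np.zeros(values.shape[0], dtype=bool)
    for i, row in enumerate(values):
        if np.ptp(row) == 0:
            flags[i] = True
            continue
        ws[i], ps[i] = stats.shapiro(row)
    out = pd.DataFrame(
        {"W": ws, "p": ps, "degenerate": flags}, index=matrix.gene_ids
    )
    out.attrs["n_below_001"] = int(np.nansum(ps < 0.001))
    return out


def prefilter(
    matrix: RatioMatrix,
    interaction_alpha: float = 0.01,
    time_alpha: float = 0.01,
) -> PrefilterResult:
    """Two-stage prefilter: exclude dye x time interaction, keep time effects.

    Stage 1 fits the model with interaction and excludes genes with raw
    interaction p below ``interaction_alpha``.  Stage 2 fits the model
    without interaction on the remaining genes and preselects those with raw
    time-effect p below ``time_alpha``.  The cuts operate on raw p-values;
    the achieved (maximum BH-adjusted) FDR at each cut is reported, not
    imposed.  Degenerate genes never enter the preselected pool.
    """
    matrix.check_balanced()
    values = matrix.matrix()
    genes = np.asarray(matrix.gene_ids)

    t_int = two_way_anova(values, matrix.time, matrix.dye, True)
    q_int = bh_fdr(t_int["p_interaction"].to_numpy())
    exclude = t_int["p_interaction"].to_numpy() < interaction_alpha
    excluded = pd.DataFrame(
        {"p": t_int["p_interaction"].to_numpy()[exclude],
         "q": q_int[exclude]},
        index=genes[exclude],
    )
    fdr_int = float(excluded["q"].max()) if len(excluded) else np.nan

    keep = ~exclude
    t_time = two_way_anova(values[keep], matrix.time, matrix.dye, False)
    p_time = t_time["p_time"].to_numpy()
    q_time = bh_fdr(p_time)
    sel = (p_time < time_alpha) & ~t_time["degenerate"].to_numpy()
    preselected = pd.DataFrame(
        {"p": p_time[sel], "q": q_time[sel]}, index=genes[keep][sel]
    )
    fdr_time = float(preselected["q"].max()) if len(preselected) else np.nan

    t_int.index = genes
    t_time.index = genes[keep]
    return PrefilterResult(
        excluded=excluded,
        preselected=preselected,
        interaction_alpha=interaction_alpha,
        time_alpha=time_alpha,
        achieved_fdr_interaction=fdr_int,
        achieved_fdr_time=fdr_time,
        anova_interaction=t_int,
        anova_time=t_time,
    )
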