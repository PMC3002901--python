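"""Normalization of two-color spot intensities into a ratio matrix.

The stage order is the standard one for spotted two-color arrays:

1. :func:`filter_background` — erase the dimmest fraction of intensities
   (per array and channel) as background,
2. :func:`compute_ma` — transform channel intensities to the MA geometry,
   orienting M as treated minus control via each array's dye label,
3. :func:`loess_normalize` — remove the intensity-dependent dye bias with a
   robust local-regression fit of M on A within each print-tip group,
4. :func:`complete_case_filter` — keep only spots detected on all 30 arrays
   and assemble the genes x samples :class:`~crhnet.containers.RatioMatrix`.
"""

from __future__ import annotations

import logging
import math
import warnings

import numpy as np
import pandas as pd

from .containers import MaMatrix, RatioMatrix, TwoColorArraySet

logger = logging.getLogger(__name__)


def loess_smooth(
    x: np.ndarray,
    y: np.ndarray,
    span: float = 0.75,
    degree: int = 2,
    robust_iters: int = 4,
) -> np.ndarray:
    """Robust local polynomial regression (loess), fitted at the data points.

    At each x0 the nearest ``ceil(span * n)`` points get tricube weights in
    scaled distance and a degree-``degree`` weighted polynomial is solved;
    ``robust_iters`` bisquare reweighting passes downweight outliers, as in
    the classical robust scatter-plot smoother.  All local systems are solved
    in one batched normal-equation call.

    Returns the fitted value at every input point.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n == 0:
        return np.empty(0)
    q = min(n, max(int(math.ceil(span * n)), degree + 1))

    dist = np.abs(x[:, None] - x[None, :])               # (n, n)
    order = np.argsort(dist, axis=1, kind="stable")[:, :q]
    dx = x[order] - x[:, None]                           # (n, q)
    dmax = np.abs(dx).max(axis=1, keepdims=True)
    dmax[dmax == 0] = 1.0
    tri = (1.0 - np.minimum(np.abs(dx) / dmax, 1.0) ** 3) ** 3

    # local design: columns 1, dx, dx^2, ... centered at each fit point
    powers = np.arange(degree + 1)
    design = dx[:, :, None] ** powers[None, None, :]     # (n, q, d+1)
    yq = y[order]

    robust = np.ones_like(tri)
    fitted = np.empty(n)
    for it in range(robust_iters + 1):
        w = tri * robust
        xtw = design * w[:, :, None]
        a = np.einsum("nqd,nqe->nde", xtw, design)
        b = np.einsum("nqd,nq->nd", xtw, yq)
        # tiny Tikhonov term keeps degenerate neighborhoods solvable
        a += 1e-12 * np.eye(degree + 1)
        beta = np.linalg.solve(a, b[..., None])[..., 0]
        fitted = beta[:, 0]
        if it == robust_iters:
            break
        resid = y - fitted
        s = np.median(np.abs(resid))
        if s <= 0:
            break
        u = np.clip(resid[order] / (6.0 * s), -1.0, 1.0)
        robust = (1.0 - u**2) ** 2
    return fitted


def filter_background(
    arrays: TwoColorArraySet, fraction: float = 0.10
) -> TwoColorArraySet:
    """Erase the dimmest ``fraction`` of intensities as background.

    The quantile is taken per array and per channel over the spots still
    present; an erased channel masks the whole spot on that array, because a
    spot with one background channel has no meaningful ratio.  Exactly
    ``floor(fraction * n_present)`` values per array/channel are erased,
    ties broken by a stable sort on (intensity, spot id).
    """
    if not 0 <= fraction < 1:
        raise ValueError("fraction must be in [0, 1)")
    out = arrays.copy()
    if fraction == 0:
        return out
    mask = out.mask.to_numpy().copy()
    spot_pos = np.arange(len(out.spots))
    total_erased = 0
    for j, _arr in enumerate(out.arrays.index):
        present0 = np.flatnonzero(mask[:, j])
        for channel in (out.cy3, out.cy5):
            present = present0
            vals = channel.to_numpy()[present, j]
            k = int(math.floor(fraction * present.size))
            if k == 0:
                continue
            if np.all(vals == vals[0]):
                warnings.warn(
                    "all intensities identical in one array/channel; "
                    "erasing the configured count by stable tie-break",
                    stacklevel=2,
                )
            order = np.lexsort((spot_pos[present], vals))
            mask[present[order[:k]], j] = False
            total_erased += k
    out.mask = pd.DataFrame(
        mask, index=out.mask.index, columns=out.mask.columns
    )
    logger.info("background filter erased %d channel values", total_erased)
    return out


def compute_ma(arrays: TwoColorArraySet) -> MaMatrix:
    """Transform channel intensities to oriented M and A values.

    M = log2(treated) - log2(control), resolved per array from the dye
    orientation; A = (log2 I_Cy3 + log2 I_Cy5) / 2.  Spots with a zero or
    missing intensity are masked.
    """
    cy3 = arrays.cy3.to_numpy(dtype=float)
    cy5 = arrays.cy5.to_numpy(dtype=float)
    mask = arrays.mask.to_numpy() & (cy3 > 0) & (cy5 > 0)
    n_zero = int((arrays.mask.to_numpy() & ~((cy3 > 0) & (cy5 > 0))).sum())
    if n_zero:
        logger.info("masked %d spots with zero intensity", n_zero)
    with np.errstate(divide="ignore", invalid="ignore"):
        l3, l5 = np.log2(cy3), np.log2(cy5)
    sign = np.where(
        arrays.arrays["dye"].to_numpy() == "treated_cy3", 1.0, -1.0
    )
    m = np.where(mask, sign[None, :] * (l3 - l5), np.nan)
    a = np.where(mask, (l3 + l5) / 2.0, np.nan)
    idx, cols = arrays.cy3.index, arrays.cy3.columns
    return MaMatrix(
        m=pd.DataFrame(m, index=idx, columns=cols),
        a=pd.DataFrame(a, index=idx, columns=cols),
        mask=pd.DataFrame(mask, index=idx, columns=cols),
        spots=arrays.spots.copy(),
        arrays=arrays.arrays.copy(),
    )


def loess_normalize(
    ma: MaMatrix,
    span: float = 0.75,
    min_group_size: int = 10,
    degree: int = 2,
    robust_iters: int = 4,
) -> MaMatrix:
    """Print-tip loess normalization: subtract the local fit of M on A.

    Within each (array, print-tip) group the robust smoother is fitted with
    the given span and the normalized ratio is the residual
    M_norm = M - M_hat(A); A is unchanged.  Groups with fewer present spots
    than ``min_group_size`` fall back to a whole-array fit (with a warning),
    since a per-tip fit would be unstable.
    """
    out = ma.copy()
    m = out.m.to_numpy()
    a = out.a.to_numpy()
    mask = out.mask.to_numpy()
    tips = out.spots["print_tip"].to_numpy()
    for j in range(m.shape[1]):
        small = []
        for tip in np.unique(tips):
            rows = np.flatnonzero((tips == tip) & mask[:, j])
            if rows.size == 0:
                continue
            if rows.size < min_group_size:
                small.append(tip)
                continue
            m[rows, j] -= loess_smooth(
                a[rows, j], m[rows, j], span, degree, robust_iters
            )
        if small:
            warnings.warn(
                f"array {out.arrays.index[j]}: print-tip group(s) {small} "
                f"below {min_group_size} spots; falling back to a "
                "whole-array fit",
                stacklevel=2,
            )
            rows = np.flatnonzero(np.isin(tips, small) & mask[:, j])
            if rows.size > degree:
                whole = np.flatnonzero(mask[:, j])
                fit = loess_smooth(
                    a[whole, j], m[whole, j], span, degree, robust_iters
                )
                lookup = dict(zip(whole, fit))
                m[rows, j] -= np.array([lookup[r] for r in rows])
    out.m = pd.DataFrame(m, index=ma.m.index, columns=ma.m.columns)
    return out


def complete_case_filter(ma: MaMatrix) -> RatioMatrix:
    """Keep spots present on every array; assemble the ratio matrix."""
    mask = ma.mask.to_numpy()
    keep = mask.all(axis=1)
    if not keep.any():
        raise ValueError("no spot is present on all arrays")
    logger.info(
        "complete-case filter kept %d of %d spots", keep.sum(), keep.size
    )
    values = ma.m.loc[keep]
    return RatioMatrix(values, ma.arrays.copy())


def normalize_pipeline(
    arrays: TwoColorArraySet,
    background_fraction: float = 0.10,
    span: float = 0.75,
    min_group_size: int = 10,
) -> RatioMatrix:
    """Full preprocessing: background filter -> MA -> loess -> complete cases."""
    filtered = filter_background(arrays, background_fraction)
    ma = compute_ma(filtered)
    norm = loess_normalize(ma, span=span, min_group_size=min_group_size)
    return complete_case_filter(norm)
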