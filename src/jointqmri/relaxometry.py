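"""Voxel-wise T1 and T2 estimation from co-registered signal stacks.

T1 is estimated from variable-flip-angle SPGR signals by the classic
linearization: with y = S/sin(a) and x = S/tan(a), the SPGR equation becomes
y = E1 x + M0 (1 - E1), so an ordinary least-squares line through the (x, y)
pairs gives E1 as the slope and T1 = -TR / ln(E1).  T2 is estimated from
multi-echo magnitudes by weighted log-linear least squares of ln S on TE
(weights S^2, which approximates nonlinear least squares under additive
noise); T2 = -1/slope.

Fits are strictly voxel-independent — no spatial regularization — and
require inputs already resampled to a common grid (spatial registration is a
precondition handled by external tools, not a stage of this package).
Voxels where the model is not identifiable (slope outside (0,1) for T1,
non-decaying signal for T2, fewer than the minimum usable samples) are
flagged invalid rather than raising.  A plausibility screen flags estimates
outside [50, 10000] ms (T1) or [1, 1000] ms (T2).
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from .grids import GridMismatchError, ParameterError, ParametricMap, RelaxometrySeries, VolumeGrid

__all__ = ["fit_t1_vfa", "fit_t2_monoexp", "summarize_map", "T1_PLAUSIBLE_MS", "T2_PLAUSIBLE_MS"]

T1_PLAUSIBLE_MS = (50.0, 10000.0)
T2_PLAUSIBLE_MS = (1.0, 1000.0)


def _check_mask(series: RelaxometrySeries, mask: Optional[VolumeGrid]) -> np.ndarray:
    if mask is None:
        return np.ones(series.grid_shape, dtype=bool)
    if mask.shape != series.grid_shape:
        raise GridMismatchError(
            f"mask shape {mask.shape} does not match series grid {series.grid_shape}"
        )
    return mask.data.astype(bool)


def _weighted_line_fit(x, y, w):
    """Per-voxel weighted OLS of y on x; returns slope, intercept, sum of weights.

    x, y, w have shape (n_samples, n_voxels); zero weight drops a sample.
    """
    sw = w.sum(axis=0)
    sw = np.where(sw > 0, sw, np.nan)
    mx = (w * x).sum(axis=0) / sw
    my = (w * y).sum(axis=0) / sw
    sxx = (w * (x - mx) ** 2).sum(axis=0)
    sxy = (w * (x - mx) * (y - my)).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = sxy / sxx
    intercept = my - slope * mx
    return slope, intercept, sxx


def fit_t1_vfa(series: RelaxometrySeries, mask: Optional[VolumeGrid] = None) -> ParametricMap:
    """Variable-flip-angle T1 map by SPGR linearization.

    Requires at least two distinct flip angles and a TR.  Per voxel inside
    the mask, fits y = S/sin(a) against x = S/tan(a); T1 = -TR/ln(slope) and
    M0 = intercept/(1 - slope), reported valid only for slope in (0, 1) and
    T1 inside the plausibility window.
    """
    if series.flip_angles_deg is None:
        raise ParameterError("fit_t1_vfa requires a variable-flip-angle series (flip angles + TR)")
    fa = np.deg2rad(series.flip_angles_deg)
    if len(np.unique(series.flip_angles_deg)) < 2:
        raise ParameterError("need at least 2 distinct flip angles")
    m = _check_mask(series, mask)

    shape = series.grid_shape
    sig = series.stack.reshape(series.n_acquisitions, -1)
    y = sig / np.sin(fa)[:, None]
    x = sig / np.tan(fa)[:, None]
    w = np.ones_like(sig)
    slope, intercept, sxx = _weighted_line_fit(x, y, w)

    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = -series.tr_ms / np.log(slope)
        m0 = intercept / (1.0 - slope)
    ok = (
        np.isfinite(slope)
        & (slope > 0.0)
        & (slope < 1.0)
        & (sxx > 0)
        & np.any(sig != 0, axis=0)
    )
    plaus = ok & (t1 >= T1_PLAUSIBLE_MS[0]) & (t1 <= T1_PLAUSIBLE_MS[1])
    t1 = np.where(ok, t1, np.nan).reshape(shape)
    m0 = np.where(ok, m0, np.nan).reshape(shape)
    valid = plaus.reshape(shape) & m

    grid = VolumeGrid(t1, series.spacing, series.affine)
    return ParametricMap(grid, grid.like(m0), grid.like(valid), "T1")


def fit_t2_monoexp(
    series: RelaxometrySeries,
    mask: Optional[VolumeGrid] = None,
    min_echoes: int = 3,
) -> ParametricMap:
    """Mono-exponential T2 map by weighted log-linear least squares.

    Echoes with non-positive signal are dropped per voxel (the log transform
    is undefined there); voxels keeping fewer than ``min_echoes`` echoes, or
    whose fitted signal does not decay, are flagged invalid.  Weights are the
    squared signals, which counteracts the heteroscedasticity introduced by
    the log transform.
    """
    if series.echo_times_ms is None:
        raise ParameterError("fit_t2_monoexp requires a multi-echo series (echo times)")
    if len(series.echo_times_ms) < 2:
        raise ParameterError("need at least 2 echo times")
    m = _check_mask(series, mask)

    shape = series.grid_shape
    sig = series.stack.reshape(series.n_acquisitions, -1)
    usable = sig > 0
    w = np.where(usable, sig**2, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        logs = np.where(usable, np.log(np.where(usable, sig, 1.0)), 0.0)
    te = np.asarray(series.echo_times_ms)[:, None] * np.ones_like(sig)
    slope, intercept, sxx = _weighted_line_fit(te, logs, w)

    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        t2 = -1.0 / slope
        s0 = np.exp(intercept)
    ok = np.isfinite(slope) & (slope < 0.0) & (sxx > 0) & (usable.sum(axis=0) >= min_echoes)
    plaus = ok & (t2 >= T2_PLAUSIBLE_MS[0]) & (t2 <= T2_PLAUSIBLE_MS[1])
    t2 = np.where(ok, t2, np.nan).reshape(shape)
    s0 = np.where(ok, s0, np.nan).reshape(shape)
    valid = plaus.reshape(shape) & m

    grid = VolumeGrid(t2, series.spacing, series.affine)
    return ParametricMap(grid, grid.like(s0), grid.like(valid), "T2")


def summarize_map(pmap: ParametricMap, labelmap: VolumeGrid) -> pd.DataFrame:
    """Per-label summary (n_valid, mean, median, sd) of a parametric map.

    Labels with zero valid voxels appear with null statistics.  Label 0 is
    treated as background and skipped.
    """
    pmap.values.require_same_grid(labelmap, "labelmap")
    labels = labelmap.data.astype(int)
    rows = []
    for label in np.unique(labels):
        if label == 0:
            continue
        sel = (labels == label) & pmap.valid_mask.data
        vals = pmap.values.data[sel]
        if vals.size == 0:
            rows.append({"label": int(label), "n_valid": 0, "mean": np.nan, "median": np.nan, "sd": np.nan})
        else:
            rows.append(
                {
                    "label": int(label),
                    "n_valid": int(vals.size),
                    "mean": float(vals.mean()),
                    "median": float(np.median(vals)),
                    "sd": float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
                }
            )
    return pd.DataFrame(rows, columns=["label", "n_valid", "mean", "median", "sd"])
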