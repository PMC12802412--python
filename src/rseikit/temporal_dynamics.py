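"""Multi-epoch dynamics of the classified ecological index.

Four views of change across an epoch-ordered series of index rasters:

* change-vector grading — the signed difference of ordinal class codes
  between two epochs (-4..4) binned into five change types;
* FROM-TO transitions — cross-tabulation of class membership with areas;
* coefficient of variation — per-cell temporal dispersion relative to the
  mean, binned into five fixed stability levels;
* Hurst exponent — rescaled-range (R/S) estimate of long-memory
  persistence per cell, binned into four persistence classes.
"""

from __future__ import annotations

from typing import List, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import DegenerateLayerError
from .raster_core import RasterGrid, ensure_aligned

#: change-type code -> label; bins on delta grade [-4,-2] / {-1} / {0} / {1} / [2,4]
CHANGE_TYPE_LABELS = {
    1: "deteriorated significantly",
    2: "deteriorated",
    3: "unchanged",
    4: "improved",
    5: "improved significantly",
}

#: CV stability levels, lower-inclusive breakpoints on [0, 1]
CV_LEVEL_BOUNDS = (0.10, 0.20, 0.30, 0.40)

#: Hurst persistence classes
HURST_CLASS_LABELS = {
    1: "strong antisustainability",   # H < 0.35
    2: "weak antisustainability",     # 0.35 <= H < 0.50
    3: "weak sustainability",         # 0.50 <= H < 0.65
    4: "strong sustainability",       # H >= 0.65
}
HURST_CLASS_BOUNDS = (0.35, 0.50, 0.65)


def _check_classes(grid: RasterGrid, which: str) -> None:
    vals = grid.valid_values
    if vals.size == 0:
        raise DegenerateLayerError(f"{which}: no valid cells")
    if np.any((vals < 1) | (vals > 5)) or np.any(vals != np.round(vals)):
        raise ValueError(f"{which}: class codes must be integers in 1..5")


def change_grade(classes_t1: RasterGrid,
                 classes_t2: RasterGrid) -> Tuple[RasterGrid, RasterGrid]:
    """Delta grade (t2 - t1) and the five-bin change-type raster.

    Cells masked in either epoch are masked in both outputs.
    """
    ensure_aligned([classes_t1, classes_t2])
    _check_classes(classes_t1, "epoch 1")
    _check_classes(classes_t2, "epoch 2")
    joint = classes_t1.valid & classes_t2.valid
    delta = np.where(joint, classes_t2.values - classes_t1.values, np.nan)
    type_codes = np.select(
        [delta <= -2, delta == -1, delta == 0, delta == 1, delta >= 2],
        [1.0, 2.0, 3.0, 4.0, 5.0], default=np.nan)
    t = classes_t1.transform
    return (RasterGrid(delta, t, classes_t1.crs_tag, ~joint),
            RasterGrid(type_codes, t, classes_t1.crs_tag, ~joint))


def transition_matrix(classes_t1: RasterGrid,
                      classes_t2: RasterGrid) -> pd.DataFrame:
    """FROM-TO table over jointly valid cells: count, km2, percent of land.

    Diagonal (unchanged) pairs are included; row/column marginals equal the
    two epochs' class histograms on the joint domain.
    """
    ensure_aligned([classes_t1, classes_t2])
    _check_classes(classes_t1, "epoch 1")
    _check_classes(classes_t2, "epoch 2")
    joint = classes_t1.valid & classes_t2.valid
    total = int(joint.sum())
    if total == 0:
        raise DegenerateLayerError("no jointly valid cells")
    c1 = classes_t1.values[joint].astype(int)
    c2 = classes_t2.values[joint].astype(int)
    cell_km2 = (classes_t1.transform.cell_size ** 2) / 1e6
    counts = pd.crosstab(pd.Series(c1, name="from_class"),
                         pd.Series(c2, name="to_class"))
    rows = []
    for f in counts.index:
        for t_ in counts.columns:
            n = int(counts.loc[f, t_])
            if n == 0:
                continue
            rows.append({"from_class": f, "to_class": t_,
                         "delta_grade": t_ - f, "count": n,
                         "area_km2": n * cell_km2,
                         "percent": 100.0 * n / total})
    return pd.DataFrame(rows).sort_values(
        ["from_class", "to_class"]).reset_index(drop=True)


def coefficient_of_variation(
    series: Sequence[RasterGrid], estimator: str = "sd"
) -> Tuple[RasterGrid, RasterGrid]:
    """Per-cell temporal CV of an epoch-ordered index series, plus levels.

    Default estimator is population standard deviation over mean; the
    ``"mad"`` variant uses the mean absolute deviation over mean.  Levels:
    [0,0.10) -> 1, [0.10,0.20) -> 2, [0.20,0.30) -> 3, [0.30,0.40) -> 4,
    everything above -> 5.  Cells with non-positive mean, or masked in any
    epoch, are masked.
    """
    if len(series) < 3:
        raise ValueError(f"need >= 3 epochs, got {len(series)}")
    ensure_aligned(series)
    stack = np.stack([g.values for g in series])
    valid = np.all([g.valid for g in series], axis=0)
    mean = stack.mean(axis=0)
    valid &= mean > 0
    if estimator == "sd":
        disp = stack.std(axis=0)  # population denominator
    elif estimator == "mad":
        disp = np.abs(stack - mean).mean(axis=0)
    else:
        raise ValueError(f"unknown CV estimator: {estimator!r}")
    cv = np.where(valid, disp / np.where(mean > 0, mean, 1.0), np.nan)
    levels = np.where(valid, np.digitize(np.nan_to_num(cv),
                                         CV_LEVEL_BOUNDS) + 1.0, np.nan)
    ref = series[0]
    return (RasterGrid(cv, ref.transform, ref.crs_tag, ~valid),
            RasterGrid(levels, ref.transform, ref.crs_tag, ~valid))


def _rs_hurst(mat: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Rescaled-range Hurst estimate for each column of an (n, m) matrix.

    For every window length tau in 2..n//2 the series is split into
    non-overlapping segments; per segment R is the range of the cumulative
    mean-adjusted sums and S the population standard deviation; R/S is
    averaged over segments with S > 0.  H is the least-squares slope of
    log(mean R/S) against log(tau), requiring >= 3 valid points, clipped
    to (0, 1].  Returns (H, valid) arrays of length m.
    """
    n, m = mat.shape
    taus = range(2, n // 2 + 1)
    log_tau, log_rs, weights = [], [], []
    for tau in taus:
        k = n // tau
        seg = mat[: k * tau].reshape(k, tau, m)
        dev = seg - seg.mean(axis=1, keepdims=True)
        cum = dev.cumsum(axis=1)
        R = cum.max(axis=1) - cum.min(axis=1)          # (k, m)
        S = seg.std(axis=1)                            # population sd
        ok = S > 0
        ratio = np.where(ok, R / np.where(ok, S, 1.0), 0.0)
        count = ok.sum(axis=0)
        mean_rs = np.where(count > 0, ratio.sum(axis=0) /
                           np.where(count > 0, count, 1), np.nan)
        w = (count > 0) & (mean_rs > 0)
        log_tau.append(np.log(tau))
        log_rs.append(np.where(w, np.log(np.where(w, mean_rs, 1.0)), 0.0))
        weights.append(w)
    x = np.asarray(log_tau)[:, None]            # (T, 1)
    y = np.asarray(log_rs)                      # (T, m)
    w = np.asarray(weights, dtype=float)        # (T, m)
    sw = w.sum(axis=0)
    valid = sw >= 3
    sx = (w * x).sum(axis=0)
    sy = (w * y).sum(axis=0)
    sxx = (w * x * x).sum(axis=0)
    sxy = (w * x * y).sum(axis=0)
    denom = sw * sxx - sx * sx
    slope = np.where(valid & (denom > 0),
                     (sw * sxy - sx * sy) / np.where(denom > 0, denom, 1.0),
                     np.nan)
    valid &= np.isfinite(slope)
    H = np.where(valid, np.clip(slope, 1e-3, 1.0), np.nan)
    return H, valid


def hurst_series(x: Sequence[float]) -> float:
    """R/S Hurst exponent of a single 1-D series (NaN if inestimable)."""
    arr = np.asarray(x, dtype=float)[:, None]
    if arr.shape[0] < 8:
        raise ValueError(f"need >= 8 observations, got {arr.shape[0]}")
    H, valid = _rs_hurst(arr)
    return float(H[0]) if valid[0] else float("nan")


def hurst_exponent(
    series: Sequence[RasterGrid],
) -> Tuple[RasterGrid, RasterGrid]:
    """Per-cell R/S Hurst map plus the four-class persistence raster.

    Classes: [0,0.35) strong antisustainability, [0.35,0.50) weak
    antisustainability, [0.50,0.65) weak sustainability, [0.65,1] strong
    sustainability.  Requires >= 8 epochs; cells masked in any epoch, or
    with fewer than 3 valid (tau, R/S) points, are masked.
    """
    if len(series) < 8:
        raise ValueError(f"need >= 8 epochs for Hurst, got {len(series)}")
    ensure_aligned(series)
    valid_all = np.all([g.valid for g in series], axis=0)
    ref = series[0]
    H_grid = np.full(ref.shape, np.nan)
    cls_grid = np.full(ref.shape, np.nan)
    if np.any(valid_all):
        mat = np.stack([g.values[valid_all] for g in series])
        H, ok = _rs_hurst(mat)
        flat = np.full(valid_all.sum(), np.nan)
        flat[ok] = H[ok]
        H_grid[valid_all] = flat
    h_valid = np.isfinite(H_grid)
    cls_grid[h_valid] = np.digitize(H_grid[h_valid], HURST_CLASS_BOUNDS) + 1.0
    return (RasterGrid(H_grid, ref.transform, ref.crs_tag, ~h_valid),
            RasterGrid(cls_grid, ref.transform, ref.crs_tag, ~h_valid))
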