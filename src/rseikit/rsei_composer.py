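"""Fuse normalized indicators into the composite ecological index (RSEI).

The index is the first principal component of the five [0,1]-normalized
indicator layers over land cells, oriented so that it increases with
greenness, then min-max rescaled to [0,1].  Eigenvector sign is arbitrary
in any solver, so instead of a conditional "1 - PC1" step the composer
applies a deterministic orientation rule: if the PC1 score is negatively
correlated with SAVI, the score is negated (equivalent after rescaling).

The PCA operates on the covariance matrix of the normalized indicators
(the standard RSEI practice); a correlation-matrix variant is available
behind ``use_correlation``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateLayerError
from .indicators import INDICATOR_ORDER, IndicatorSet
from .raster_core import RasterGrid, ensure_aligned

#: class code -> (roman numeral, descriptive label)
CLASS_LABELS = {
    1: ("I", "bad"),
    2: ("II", "poor"),
    3: ("III", "moderate"),
    4: ("IV", "good"),
    5: ("V", "excellent"),
}

#: lower-inclusive interior class boundaries on the [0, 1] index
CLASS_BOUNDS = (0.20, 0.40, 0.60, 0.80)


@dataclass
class PcaResult:
    """Loadings, eigenvalues and contribution rates of the indicator PCA.

    ``loadings`` holds one unit-norm row per component, columns in
    ``indicator_names`` order; ``contribution_rates`` are eigenvalue shares
    summing to 1, sorted descending.
    """

    loadings: np.ndarray
    eigenvalues: np.ndarray
    contribution_rates: np.ndarray
    indicator_names: Tuple[str, ...] = INDICATOR_ORDER
    oriented: bool = False

    def table(self) -> pd.DataFrame:
        """Per-component report: eigenvalue, contribution and loadings."""
        rows = []
        for i in range(len(self.eigenvalues)):
            row = {"component": f"PC{i + 1}",
                   "eigenvalue": self.eigenvalues[i],
                   "contribution_rate": self.contribution_rates[i]}
            row.update({name: self.loadings[i, j]
                        for j, name in enumerate(self.indicator_names)})
            rows.append(row)
        return pd.DataFrame(rows)


@dataclass
class RseiResult:
    """Composite index, class raster and supporting statistics for one epoch."""

    rsei: RasterGrid
    classes: RasterGrid
    pca: PcaResult
    class_areas: pd.DataFrame
    indicator_correlations: pd.Series
    epoch_label: str = ""


def pca_fit(matrix: np.ndarray,
            indicator_names: Optional[Sequence[str]] = None,
            use_correlation: bool = False) -> PcaResult:
    """Eigen-decompose the covariance of an (n_samples, p) value matrix.

    Components are sorted by eigenvalue descending; contribution rates are
    eigenvalue shares of the trace.  Works for any p >= 2, so arbitrary
    indicator subsets can be fused.
    """
    X = np.asarray(matrix, dtype=np.float64)
    if X.ndim != 2:
        raise ValueError("matrix must be 2-D (samples x indicators)")
    n, p = X.shape
    if n < p + 1:
        raise DegenerateLayerError(
            f"need more samples ({n}) than indicators ({p}) for PCA")
    cov = np.cov(X, rowvar=False)
    if use_correlation:
        sd = np.sqrt(np.diag(cov))
        if np.any(sd == 0):
            raise DegenerateLayerError("constant indicator column")
        cov = cov / np.outer(sd, sd)
    if not np.all(np.isfinite(cov)):
        raise DegenerateLayerError("non-finite covariance matrix")
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    loadings = eigvecs[:, order].T  # row i = component i
    total = eigvals.sum()
    if total <= 0:
        raise DegenerateLayerError("zero total variance")
    names = tuple(indicator_names) if indicator_names is not None \
        else tuple(f"x{i}" for i in range(p))
    return PcaResult(loadings=loadings, eigenvalues=eigvals,
                     contribution_rates=eigvals / total,
                     indicator_names=names)


def fit_pca(indset: IndicatorSet, use_correlation: bool = False) -> PcaResult:
    """PCA of a normalized indicator set over its land cells."""
    if not indset.normalized:
        raise ValueError("IndicatorSet must be normalized before PCA")
    X, land = indset.matrix()
    if land.sum() < len(INDICATOR_ORDER) + 1:
        raise DegenerateLayerError(
            f"only {int(land.sum())} land cells; too few for PCA")
    return pca_fit(X, indicator_names=INDICATOR_ORDER,
                   use_correlation=use_correlation)


def compose_rsei(pca: PcaResult, indset: IndicatorSet) -> RseiResult:
    """PC1 scores, orientation, [0,1] rescale, classification and stats."""
    X, land = indset.matrix()
    Xc = X - X.mean(axis=0)
    scores = Xc @ pca.loadings[0]
    if np.ptp(scores) == 0:
        raise DegenerateLayerError("constant PC1 score field")
    savi_col = X[:, pca.indicator_names.index("savi")]
    r = np.corrcoef(scores, savi_col)[0, 1]
    oriented = bool(r < 0)
    if oriented:
        scores = -scores
    pca = PcaResult(loadings=pca.loadings.copy(),
                    eigenvalues=pca.eigenvalues,
                    contribution_rates=pca.contribution_rates,
                    indicator_names=pca.indicator_names, oriented=oriented)
    if oriented:
        pca.loadings[0] = -pca.loadings[0]

    rescaled = (scores - scores.min()) / (scores.max() - scores.min())
    ref = indset.savi
    vals = np.full(ref.shape, np.nan)
    vals[land] = rescaled
    rsei = RasterGrid(vals, ref.transform, ref.crs_tag, ~land)
    classes = classify_rsei(rsei)
    areas = class_area_stats(classes)
    corr = pd.Series(
        {name: float(np.corrcoef(rescaled, X[:, j])[0, 1])
         for j, name in enumerate(pca.indicator_names)},
        name="pearson_r")
    return RseiResult(rsei=rsei, classes=classes, pca=pca, class_areas=areas,
                      indicator_correlations=corr,
                      epoch_label=indset.epoch_label)


def classify_rsei(rsei: RasterGrid) -> RasterGrid:
    """Five ecological-quality grades with lower-inclusive boundaries.

    I (bad) [0, 0.2), II (poor) [0.2, 0.4), III (moderate) [0.4, 0.6),
    IV (good) [0.6, 0.8), V (excellent) [0.8, 1.0] — codes 1..5.
    """
    vals = rsei.valid_values
    eps = 1e-9
    if vals.size and (vals.min() < -eps or vals.max() > 1 + eps):
        raise ValueError(
            f"index values outside [0, 1]: range [{vals.min()}, {vals.max()}]")
    clipped = np.clip(rsei.values, 0.0, 1.0)
    codes = np.digitize(clipped, CLASS_BOUNDS, right=False) + 1.0
    codes = np.where(rsei.valid, codes, np.nan)
    return RasterGrid(codes, rsei.transform, rsei.crs_tag,
                      rsei.nodata_mask.copy())


def class_area_stats(classes: RasterGrid) -> pd.DataFrame:
    """Per-class cell count, area in km2 and percentage of land."""
    valid = classes.valid
    total = int(valid.sum())
    if total == 0:
        raise DegenerateLayerError("class raster has no valid cells")
    cell_km2 = (classes.transform.cell_size ** 2) / 1e6
    rows = []
    codes = classes.values[valid].astype(int)
    for code in range(1, 6):
        count = int(np.sum(codes == code))
        roman, label = CLASS_LABELS[code]
        rows.append({"class_code": code, "class": roman, "label": label,
                     "count": count, "area_km2": count * cell_km2,
                     "percent": 100.0 * count / total})
    return pd.DataFrame(rows)


def raster_correlation(a: RasterGrid, b: RasterGrid) -> float:
    """Pearson r between two rasters over jointly unmasked cells."""
    ensure_aligned([a, b])
    joint = a.valid & b.valid
    if joint.sum() < 3:
        raise DegenerateLayerError(
            f"only {int(joint.sum())} joint cells; need >= 3 for correlation")
    r, _ = stats.pearsonr(a.values[joint], b.values[joint])
    return float(r)
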