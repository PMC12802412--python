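"""Ecological component indicators derived from a surface-reflectance stack.

Five indicators enter the composite index, computed over non-water land
cells only:

* greenness  — SAVI, soil-adjusted vegetation index (NIR/red with soil
  constant L, default 0.5);
* humidity   — SWCI, shortwave-infrared surface water content index;
* dryness    — NDBBI, normalized-difference bareness and built-up index;
* heat       — LST in Celsius from thermal DN (0.02 * DN - 273.15);
* salinity   — CSI, the mean of three [0,1]-normalized salinity indices
  (SI-T, NDSI, SI4).

Open water distorts both the min-max normalization and the PCA weights of
the composite, so water cells are detected with MNDWI = (green - SWIR1) /
(green + SWIR1) and masked before anything else is computed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np

from .errors import DegenerateLayerError
from .raster_core import BandStack, RasterGrid, minmax_normalize

INDICATOR_ORDER: Tuple[str, ...] = ("savi", "swci", "ndbbi", "lst", "csi")

# MODIS scaled reflectance occasionally carries out-of-range artifacts;
# values outside this window are treated as nodata before any index math.
REFLECTANCE_VALID = (-0.01, 1.6)


@dataclass
class IndicatorSet:
    """Water-masked indicator layers for one epoch, indicator order
    (savi, swci, ndbbi, lst, csi)."""

    savi: RasterGrid
    swci: RasterGrid
    ndbbi: RasterGrid
    lst: RasterGrid
    csi: RasterGrid
    water_mask: np.ndarray
    normalized: bool = False
    epoch_label: str = ""

    def layers(self) -> Dict[str, RasterGrid]:
        return {name: getattr(self, name) for name in INDICATOR_ORDER}

    @property
    def land_mask(self) -> np.ndarray:
        """True where every indicator layer is valid (non-water land)."""
        land = np.ones(self.savi.shape, dtype=bool)
        for g in self.layers().values():
            land &= g.valid
        return land

    def matrix(self) -> Tuple[np.ndarray, np.ndarray]:
        """(n_land, 5) value matrix in indicator order plus the land mask."""
        land = self.land_mask
        cols = [getattr(self, name).values[land] for name in INDICATOR_ORDER]
        return np.column_stack(cols), land


def _clean_stack(stack: BandStack) -> BandStack:
    """Mask reflectance values outside the validity window."""
    lo, hi = REFLECTANCE_VALID
    bands = {}
    for name, g in stack.bands.items():
        bad = (g.values < lo) | (g.values > hi)
        bands[name] = g.with_values(np.where(bad, np.nan, g.values), bad)
    return BandStack(bands, stack.lst_dn.copy(), stack.epoch_label)


def _ratio(num: np.ndarray, den: np.ndarray, base_mask: np.ndarray,
           positive_denominator: bool = False) -> Tuple[np.ndarray, np.ndarray]:
    """Safe element-wise ratio; zero (or non-positive) denominators mask."""
    mask = base_mask.copy()
    if positive_denominator:
        mask |= ~(den > 0)
    else:
        mask |= den == 0
    out = np.full(num.shape, np.nan)
    np.divide(num, den, out=out, where=~mask)
    return out, mask


def compute_mndwi(stack: BandStack) -> RasterGrid:
    """MNDWI = (b4 - b6) / (b4 + b6); positive over open water."""
    b4, b6 = stack.bands["b4"], stack.bands["b6"]
    base = b4.nodata_mask | b6.nodata_mask
    out, mask = _ratio(b4.values - b6.values, b4.values + b6.values, base)
    return RasterGrid(out, stack.transform, stack.crs_tag, mask)


def water_mask(mndwi: RasterGrid, threshold: float = 0.0) -> np.ndarray:
    """Boolean lattice, True where MNDWI exceeds the water threshold."""
    return mndwi.valid & (mndwi.values > threshold)


def compute_savi(stack: BandStack, L: float = 0.5) -> RasterGrid:
    """SAVI = (1 + L)(b2 - b1) / (b1 + b2 + L).  With L = 0 this is NDVI."""
    if L < 0:
        raise ValueError(f"soil adjustment L must be >= 0, got {L}")
    b1, b2 = stack.bands["b1"], stack.bands["b2"]
    base = b1.nodata_mask | b2.nodata_mask
    out, mask = _ratio((1.0 + L) * (b2.values - b1.values),
                       b1.values + b2.values + L, base,
                       positive_denominator=True)
    return RasterGrid(out, stack.transform, stack.crs_tag, mask)


def compute_swci(stack: BandStack) -> RasterGrid:
    """SWCI = (b6 - b7) / (b6 + b7)."""
    b6, b7 = stack.bands["b6"], stack.bands["b7"]
    base = b6.nodata_mask | b7.nodata_mask
    out, mask = _ratio(b6.values - b7.values, b6.values + b7.values, base)
    return RasterGrid(out, stack.transform, stack.crs_tag, mask)


def compute_ndbbi(stack: BandStack, grouping: str = "mean") -> RasterGrid:
    """Bareness/built-up index from SWIR1, NIR and green.

    ``grouping="mean"`` (default): (1.5 b6 - (b2 + b4)/2) /
    (1.5 b6 + (b2 + b4)/2), the original NDBBI definition.
    ``grouping="literal"``: (1.5 b6 - b2 + b4/2) / (1.5 b6 + b2 + b4/2),
    an alternative reading of the loosely typeset formula, kept for
    reproducibility studies.
    """
    b2, b4, b6 = stack.bands["b2"], stack.bands["b4"], stack.bands["b6"]
    base = b2.nodata_mask | b4.nodata_mask | b6.nodata_mask
    if grouping == "mean":
        half = (b2.values + b4.values) / 2.0
        num, den = 1.5 * b6.values - half, 1.5 * b6.values + half
    elif grouping == "literal":
        num = 1.5 * b6.values - b2.values + b4.values / 2.0
        den = 1.5 * b6.values + b2.values + b4.values / 2.0
    else:
        raise ValueError(f"unknown NDBBI grouping: {grouping!r}")
    out, mask = _ratio(num, den, base)
    return RasterGrid(out, stack.transform, stack.crs_tag, mask)


def compute_lst(stack: BandStack, scale: float = 0.02,
                offset: float = -273.15) -> RasterGrid:
    """LST in Celsius from thermal DN: scale * DN + offset."""
    dn = stack.lst_dn
    out = np.where(dn.valid, scale * dn.values + offset, np.nan)
    return RasterGrid(out, stack.transform, stack.crs_tag,
                      dn.nodata_mask.copy())


def compute_csi(stack: BandStack,
                mask: Optional[np.ndarray] = None) -> RasterGrid:
    """Comprehensive salinity index: mean of three normalized sub-indices.

    SI-T = (b1/b2)*100, NDSI = (b1-b2)/(b1+b2), SI4 = b6/b2; each is
    min-max normalized to [0,1] over the unmasked (land) cells of this
    epoch, and CSI is their cell-wise mean — so CSI lies in [0,1] by
    construction.
    """
    b1, b2, b6 = stack.bands["b1"], stack.bands["b2"], stack.bands["b6"]
    base = b1.nodata_mask | b2.nodata_mask | b6.nodata_mask
    if mask is not None:
        base = base | np.asarray(mask, dtype=bool)
    si_t, m1 = _ratio(b1.values * 100.0, b2.values, base,
                      positive_denominator=True)
    ndsi, m2 = _ratio(b1.values - b2.values, b1.values + b2.values, base)
    si4, m3 = _ratio(b6.values, b2.values, base, positive_denominator=True)
    joint = m1 | m2 | m3
    subs = []
    for name, arr in (("SI-T", si_t), ("NDSI", ndsi), ("SI4", si4)):
        g = RasterGrid(arr, stack.transform, stack.crs_tag, joint)
        subs.append(minmax_normalize(g, name=f"CSI sub-index {name}"))
    csi = (subs[0].values + subs[1].values + subs[2].values) / 3.0
    return RasterGrid(csi, stack.transform, stack.crs_tag, joint)


def build_indicator_set(stack: BandStack, water_threshold: float = 0.0,
                        savi_L: float = 0.5,
                        ndbbi_grouping: str = "mean") -> IndicatorSet:
    """Water-mask a stack, compute the five indicators, normalize each.

    Water cells (MNDWI > threshold) are masked in every layer, then each
    indicator is min-max rescaled to [0,1] over the remaining land cells,
    giving the dimension-free inputs the PCA composition expects.
    """
    stack = _clean_stack(stack)
    mndwi = compute_mndwi(stack)
    water = water_mask(mndwi, water_threshold)
    invalid = stack.invalid_mask
    if not np.any(~invalid & ~water):
        raise DegenerateLayerError(
            f"epoch {stack.epoch_label!r}: all-water scene, no land cells")

    raw = {
        "savi": compute_savi(stack, savi_L),
        "swci": compute_swci(stack),
        "ndbbi": compute_ndbbi(stack, ndbbi_grouping),
        "lst": compute_lst(stack),
        "csi": compute_csi(stack, mask=water),
    }
    norm = {}
    for name, grid in raw.items():
        masked = grid.with_values(grid.values, extra_mask=water)
        norm[name] = minmax_normalize(masked, name=name)
    return IndicatorSet(savi=norm["savi"], swci=norm["swci"],
                        ndbbi=norm["ndbbi"], lst=norm["lst"],
                        csi=norm["csi"], water_mask=water, normalized=True,
                        epoch_label=stack.epoch_label)
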