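"""Grid data model and GeoTIFF I/O shared by every analysis stage.

The toolkit works on pre-aligned, north-up, square-cell rasters in a
projected CRS.  It never resamples or reprojects; alignment is validated
explicitly and downstream operations raise on misaligned inputs.  Cells are
equal-area, so the area of any cell set is ``count * cell_size**2``.

Nodata handling: every :class:`RasterGrid` carries a boolean ``nodata_mask``
(True = invalid).  Masked cells are excluded from every statistic computed
downstream, and any arithmetic with a masked operand yields a masked cell.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np
import tifffile

from .errors import AlignmentError, DegenerateLayerError, RasterFormatError

# GeoTIFF / GDAL tag codes
_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113

_NODATA_SENTINEL = -9999.0


@dataclass(frozen=True)
class GridTransform:
    """North-up raster georeference: top-left corner and square cell size."""

    origin_x: float
    origin_y: float
    cell_size: float

    def __post_init__(self) -> None:
        if not self.cell_size > 0:
            raise ValueError(f"cell_size must be > 0, got {self.cell_size}")


@dataclass
class RasterGrid:
    """A single-band raster: 2-D values, georeference, CRS tag, nodata mask."""

    values: np.ndarray
    transform: GridTransform
    crs_tag: str = ""
    nodata_mask: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError(f"values must be 2-D, got ndim={self.values.ndim}")
        if self.nodata_mask is None:
            self.nodata_mask = ~np.isfinite(self.values)
        else:
            self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
            if self.nodata_mask.shape != self.values.shape:
                raise ValueError(
                    "nodata_mask shape "
                    f"{self.nodata_mask.shape} != values shape {self.values.shape}"
                )
            self.nodata_mask = self.nodata_mask | ~np.isfinite(self.values)

    @property
    def shape(self) -> tuple:
        return self.values.shape

    @property
    def valid(self) -> np.ndarray:
        """Boolean lattice of usable cells (True = valid)."""
        return ~self.nodata_mask

    @property
    def valid_values(self) -> np.ndarray:
        """1-D array of values at unmasked cells."""
        return self.values[self.valid]

    def with_values(
        self, values: np.ndarray, extra_mask: Optional[np.ndarray] = None
    ) -> "RasterGrid":
        """New grid with the same geometry, optionally a widened mask."""
        mask = self.nodata_mask.copy()
        if extra_mask is not None:
            mask |= np.asarray(extra_mask, dtype=bool)
        return RasterGrid(np.asarray(values, dtype=np.float64), self.transform,
                          self.crs_tag, mask)

    def copy(self) -> "RasterGrid":
        return RasterGrid(self.values.copy(), self.transform, self.crs_tag,
                          self.nodata_mask.copy())


@dataclass
class BandStack:
    """Aligned surface-reflectance bands plus the LST DN grid for one epoch.

    ``bands`` maps the sensor band names b1 (red), b2 (NIR), b4 (green),
    b6 (SWIR1), b7 (SWIR2) to reflectance grids scaled to roughly [0, 1];
    ``lst_dn`` holds raw thermal DN values.
    """

    bands: Dict[str, RasterGrid]
    lst_dn: RasterGrid
    epoch_label: str = ""

    REQUIRED = ("b1", "b2", "b4", "b6", "b7")

    def __post_init__(self) -> None:
        missing = [b for b in self.REQUIRED if b not in self.bands]
        if missing:
            raise ValueError(f"BandStack missing bands: {missing}")
        ensure_aligned(list(self.bands.values()) + [self.lst_dn])

    @property
    def shape(self) -> tuple:
        return self.lst_dn.shape

    @property
    def transform(self) -> GridTransform:
        return self.lst_dn.transform

    @property
    def crs_tag(self) -> str:
        return self.lst_dn.crs_tag

    @property
    def invalid_mask(self) -> np.ndarray:
        """Union of member nodata masks — the stack's invalid set."""
        mask = self.lst_dn.nodata_mask.copy()
        for g in self.bands.values():
            mask |= g.nodata_mask
        return mask


@dataclass
class AlignmentReport:
    """Result of comparing grid geometries; passes iff no mismatches."""

    ok: bool
    mismatches: List[str] = field(default_factory=list)


def align_check(grids: Sequence[RasterGrid]) -> AlignmentReport:
    """Check that all grids share shape, transform and CRS tag exactly."""
    if len(grids) == 0:
        raise ValueError("align_check requires at least one grid")
    ref = grids[0]
    mismatches: List[str] = []
    for i, g in enumerate(grids[1:], start=1):
        if g.shape != ref.shape:
            mismatches.append(f"grid {i}: shape {g.shape} != {ref.shape}")
        t, rt = g.transform, ref.transform
        if t.cell_size != rt.cell_size:
            mismatches.append(
                f"grid {i}: cell_size {t.cell_size} != {rt.cell_size}")
        if (t.origin_x, t.origin_y) != (rt.origin_x, rt.origin_y):
            mismatches.append(
                f"grid {i}: origin ({t.origin_x}, {t.origin_y}) != "
                f"({rt.origin_x}, {rt.origin_y})")
        if g.crs_tag != ref.crs_tag:
            mismatches.append(f"grid {i}: crs {g.crs_tag!r} != {ref.crs_tag!r}")
    return AlignmentReport(ok=not mismatches, mismatches=mismatches)


def ensure_aligned(grids: Sequence[RasterGrid]) -> None:
    """Raise :class:`AlignmentError` if the grids do not share geometry."""
    report = align_check(grids)
    if not report.ok:
        raise AlignmentError("; ".join(report.mismatches))


def minmax_normalize(
    grid: RasterGrid,
    mask: Optional[np.ndarray] = None,
    name: str = "layer",
) -> RasterGrid:
    """Rescale a grid to [0, 1] over its unmasked cells.

    ``out = (x - min) / (max - min)`` computed over cells that are neither
    nodata nor excluded by ``mask`` (True = exclude).  Masked cells stay
    masked.  A constant layer raises :class:`DegenerateLayerError` naming it.
    """
    invalid = grid.nodata_mask.copy()
    if mask is not None:
        invalid |= np.asarray(mask, dtype=bool)
    vals = grid.values[~invalid]
    if vals.size < 2:
        raise DegenerateLayerError(
            f"{name}: need >= 2 unmasked cells, got {vals.size}")
    lo, hi = float(vals.min()), float(vals.max())
    if not hi > lo:
        raise DegenerateLayerError(
            f"{name}: degenerate range (max == min == {lo})")
    out = np.full(grid.shape, np.nan)
    out[~invalid] = (grid.values[~invalid] - lo) / (hi - lo)
    return RasterGrid(out, grid.transform, grid.crs_tag, invalid)


def read_geotiff(path) -> RasterGrid:
    """Read a single-band GeoTIFF into a :class:`RasterGrid`.

    Cells equal to the file's GDAL nodata sentinel (or non-finite) are
    masked.  Missing files, multi-band files and files without a
    georeference raise :class:`RasterFormatError`.
    """
    try:
        tif = tifffile.TiffFile(str(path))
    except FileNotFoundError as exc:
        raise RasterFormatError(f"file not found: {path}") from exc
    except Exception as exc:  # not a TIFF at all
        raise RasterFormatError(f"not a readable GeoTIFF: {path} ({exc})") from exc
    with tif:
        if len(tif.pages) != 1:
            raise RasterFormatError(
                f"{path}: expected single-band file, found {len(tif.pages)} pages")
        page = tif.pages[0]
        values = page.asarray()
        if values.ndim != 2:
            raise RasterFormatError(
                f"{path}: expected single-band image, got shape {values.shape}")
        tags = page.tags
        if _TAG_MODEL_PIXEL_SCALE not in tags or _TAG_MODEL_TIEPOINT not in tags:
            raise RasterFormatError(f"{path}: missing GeoTIFF transform tags")
        scale = tags[_TAG_MODEL_PIXEL_SCALE].value
        tie = tags[_TAG_MODEL_TIEPOINT].value
        transform = GridTransform(origin_x=float(tie[3]), origin_y=float(tie[4]),
                                  cell_size=float(scale[0]))
        crs_tag = ""
        desc = page.description or ""
        if desc:
            try:
                crs_tag = json.loads(desc).get("crs", "")
            except (ValueError, AttributeError):
                crs_tag = ""
        values = np.asarray(values, dtype=np.float64)
        mask = ~np.isfinite(values)
        if _TAG_GDAL_NODATA in tags:
            try:
                sentinel = float(tags[_TAG_GDAL_NODATA].value)
                if np.isfinite(sentinel):
                    mask |= values == sentinel
            except ValueError:
                pass
        values = np.where(mask, np.nan, values)
    return RasterGrid(values, transform, crs_tag, mask)


def write_geotiff(grid: RasterGrid, path) -> str:
    """Write a grid as a float32 single-band GeoTIFF with nodata tag.

    Masked cells are stored as the nodata sentinel; ``read_geotiff`` is the
    inverse on values, mask and transform.
    """
    data = np.where(grid.nodata_mask, _NODATA_SENTINEL, grid.values)
    data = data.astype(np.float32)
    t = grid.transform
    extratags = [
        (_TAG_MODEL_PIXEL_SCALE, "d", 3, (t.cell_size, t.cell_size, 0.0)),
        (_TAG_MODEL_TIEPOINT, "d", 6,
         (0.0, 0.0, 0.0, t.origin_x, t.origin_y, 0.0)),
        (_TAG_GDAL_NODATA, "s", 0, str(_NODATA_SENTINEL)),
    ]
    description = json.dumps({"crs": grid.crs_tag})
    try:
        tifffile.imwrite(str(path), data, extratags=extratags,
                         description=description)
    except (OSError, PermissionError) as exc:
        raise RasterFormatError(f"cannot write {path}: {exc}") from exc
    return str(path)
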