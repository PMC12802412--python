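"""Seeded generator of synthetic band stacks with known ground truth.

Every pipeline stage can be exercised without a satellite archive: the
generator emits multi-epoch reflectance stacks driven by a smooth latent
ecological-quality field E in [0, 1], contiguous water bodies, an optional
monotone degradation/improvement trend, and driver rasters constructed to
a target between-strata variance fraction (target q).

Band model (reflectance = intercept + slope * E + noise, clipped to
[0.01, 0.95]): NIR increases with E while red, green and both SWIR bands
decrease, so SAVI and SWCI increase with ecological quality and NDBBI,
CSI and LST decrease — the sign structure a real arid-land scene shows.
Thermal DN encodes LST = dT * (1 - E) + T0 Celsius at the standard 0.02
scaling.  All randomness flows from a single NumPy PCG64 generator seeded
by the spec, so identical specs give bit-identical scenes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy import ndimage

from .errors import DegenerateLayerError
from .raster_core import BandStack, GridTransform, RasterGrid

#: per-band (intercept, slope-on-E) of the reflectance model
BAND_MODEL: Dict[str, Tuple[float, float]] = {
    "b1": (0.25, -0.15),   # red: brighter bare soil at low quality
    "b2": (0.10, +0.40),   # NIR: vegetation plateau
    "b4": (0.12, -0.04),   # green
    "b6": (0.35, -0.20),   # SWIR1: dry soil bright
    "b7": (0.28, -0.18),   # SWIR2
}

REFLECTANCE_CLIP = (0.01, 0.95)
WATER_OVERRIDES = {"b4": 0.30, "b6": 0.05}  # MNDWI strongly positive

LST_SCALE = 0.02


@dataclass(frozen=True)
class SceneSpec:
    """Generator conditions: grid geometry, seed, texture and dynamics.

    ``smoothness`` is the latent field's correlation length in cells,
    ``noise_sd`` the per-band reflectance noise, ``trend`` the per-epoch
    additive drift applied to the latent field (negative = degradation).
    """

    shape: Tuple[int, int] = (128, 128)
    cell_size: float = 500.0
    seed: int = 0
    smoothness: float = 8.0
    noise_sd: float = 0.01
    water_fraction: float = 0.05
    trend: float = 0.0
    epochs: int = 12
    t0_celsius: float = 18.0
    dt_celsius: float = 20.0
    crs_tag: str = "EPSG:32649"

    def __post_init__(self) -> None:
        if not 0 <= self.water_fraction < 0.5:
            raise ValueError(
                f"water_fraction must be in [0, 0.5), got {self.water_fraction}")

    @property
    def transform(self) -> GridTransform:
        return GridTransform(500000.0, 4600000.0, self.cell_size)

    def epoch_labels(self) -> List[str]:
        return [str(2001 + 2 * t) for t in range(self.epochs)]


@dataclass
class SceneTruth:
    """Ground truth emitted alongside data, enough to score recovery."""

    latent: List[RasterGrid]
    water_mask: np.ndarray
    epoch_labels: List[str]
    spec: SceneSpec
    metadata: Dict = field(default_factory=dict)


def _latent_field(rng: np.random.Generator, spec: SceneSpec) -> np.ndarray:
    noise = rng.standard_normal(spec.shape)
    if spec.smoothness > 0:
        noise = ndimage.gaussian_filter(noise, sigma=spec.smoothness,
                                        mode="reflect")
    lo, hi = noise.min(), noise.max()
    if not hi > lo:
        raise DegenerateLayerError("degenerate latent field")
    return (noise - lo) / (hi - lo)


def _water_blobs(rng: np.random.Generator, shape: Tuple[int, int],
                 fraction: float) -> np.ndarray:
    """Disk-shaped water bodies grown to roughly the target cell fraction."""
    water = np.zeros(shape, dtype=bool)
    if fraction <= 0:
        return water
    rows, cols = shape
    target = int(round(fraction * rows * cols))
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    max_r = max(2, min(rows, cols) // 8)
    for _ in range(200):
        remaining = target - int(water.sum())
        if remaining <= 0:
            break
        radius = int(np.clip(np.sqrt(remaining / np.pi), 2, max_r))
        cy = rng.integers(radius, rows - radius)
        cx = rng.integers(radius, cols - radius)
        water |= (rr - cy) ** 2 + (cc - cx) ** 2 <= radius ** 2
    return water


def _stack_from_latent(E: np.ndarray, water: np.ndarray,
                       rng: np.random.Generator, spec: SceneSpec,
                       label: str) -> BandStack:
    lo, hi = REFLECTANCE_CLIP
    bands = {}
    for name, (a, b) in BAND_MODEL.items():
        vals = a + b * E
        if spec.noise_sd > 0:
            vals = vals + rng.normal(0.0, spec.noise_sd, size=E.shape)
        vals = np.clip(vals, lo, hi)
        if name in WATER_OVERRIDES:
            vals = np.where(water, WATER_OVERRIDES[name], vals)
        bands[name] = RasterGrid(vals, spec.transform, spec.crs_tag)
    lst_c = spec.dt_celsius * (1.0 - E) + spec.t0_celsius
    dn = (lst_c + 273.15) / LST_SCALE
    lst_dn = RasterGrid(dn, spec.transform, spec.crs_tag)
    return BandStack(bands=bands, lst_dn=lst_dn, epoch_label=label)


def simulate_scene(spec: SceneSpec) -> Tuple[BandStack, SceneTruth]:
    """One epoch: latent field, water bodies, band stack and truth."""
    rng = np.random.default_rng(spec.seed)
    E = _latent_field(rng, spec)
    water = _water_blobs(rng, spec.shape, spec.water_fraction)
    label = spec.epoch_labels()[0]
    stack = _stack_from_latent(E, water, rng, spec, label)
    truth = SceneTruth(
        latent=[RasterGrid(E, spec.transform, spec.crs_tag)],
        water_mask=water, epoch_labels=[label], spec=spec,
        metadata={"generator": "numpy PCG64", "band_model": BAND_MODEL})
    return stack, truth


def simulate_timeseries(spec: SceneSpec) -> Tuple[List[BandStack], SceneTruth]:
    """Epoch-ordered stacks sharing one base latent field and water mask.

    Epoch t uses E_t = clip(E + t * trend, 0, 1); band noise is redrawn
    per epoch from the same seeded generator stream.
    """
    if spec.epochs < 3:
        raise ValueError(f"need >= 3 epochs, got {spec.epochs}")
    rng = np.random.default_rng(spec.seed)
    E0 = _latent_field(rng, spec)
    water = _water_blobs(rng, spec.shape, spec.water_fraction)
    labels = spec.epoch_labels()
    stacks, latents = [], []
    for t, label in enumerate(labels):
        Et = np.clip(E0 + t * spec.trend, 0.0, 1.0)
        stacks.append(_stack_from_latent(Et, water, rng, spec, label))
        latents.append(RasterGrid(Et, spec.transform, spec.crs_tag))
    truth = SceneTruth(latent=latents, water_mask=water, epoch_labels=labels,
                       spec=spec,
                       metadata={"generator": "numpy PCG64",
                                 "band_model": BAND_MODEL})
    return stacks, truth


@dataclass
class DriverSimulation:
    """A driver raster plus the response it explains at the target q."""

    driver: RasterGrid
    response: RasterGrid
    labels: np.ndarray
    target_q: float
    sigma: float
    stratum_means: np.ndarray


def simulate_driver(E: RasterGrid, k: int, target_q: float, seed: int = 0,
                    continuous: bool = False) -> DriverSimulation:
    """Build a driver stratification of E whose population q equals target_q.

    Strata are quantile bins of the latent field; the validation response
    is y = mu_stratum + e with e ~ Normal(0, sigma), where sigma^2 =
    Var_between * (1 - q0) / q0 — so the expected q of y given the strata
    is exactly the target.  The emitted driver raster holds the stratum
    codes, or with ``continuous=True`` bin midpoints plus uniform
    within-bin jitter (so re-discretization can recover the strata).
    """
    if not 0 < target_q < 1:
        raise ValueError(f"target_q must be in (0, 1), got {target_q}")
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    rng = np.random.default_rng(seed)
    valid = E.valid
    e = E.values[valid]
    if np.unique(e).size < k:
        raise DegenerateLayerError("latent field too degenerate to stratify")
    edges = np.quantile(e, np.arange(1, k) / k)
    edges = np.unique(edges)
    labels_flat = np.searchsorted(edges, e, side="right")
    n = e.size
    cnt = np.bincount(labels_flat)
    sums = np.bincount(labels_flat, weights=e)
    mu = np.divide(sums, cnt, out=np.zeros_like(sums), where=cnt > 0)
    grand = e.mean()
    var_between = float(np.sum(cnt * (mu[: cnt.size] - grand) ** 2) / n)
    if var_between <= 0:
        raise DegenerateLayerError("zero between-strata variance")
    sigma = float(np.sqrt(var_between * (1.0 - target_q) / target_q))
    y_flat = mu[labels_flat] + rng.normal(0.0, sigma, size=n)

    full_edges = np.concatenate([[e.min()], edges, [e.max()]])
    if continuous:
        lo = full_edges[labels_flat]
        hi = full_edges[labels_flat + 1]
        drv_flat = lo + rng.uniform(0.0, 1.0, size=n) * (hi - lo)
    else:
        drv_flat = labels_flat.astype(float)

    def expand(flat: np.ndarray) -> np.ndarray:
        out = np.full(E.shape, np.nan)
        out[valid] = flat
        return out

    labels_grid = np.full(E.shape, -1, dtype=np.int64)
    labels_grid[valid] = labels_flat
    driver = RasterGrid(expand(drv_flat), E.transform, E.crs_tag, ~valid)
    response = RasterGrid(expand(y_flat), E.transform, E.crs_tag, ~valid)
    return DriverSimulation(driver=driver, response=response,
                            labels=labels_grid, target_q=target_q,
                            sigma=sigma, stratum_means=mu)
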