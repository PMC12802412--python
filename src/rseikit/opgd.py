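"""Optimal-parameter geographical detector (OPGD).

The geographical detector quantifies how much a spatial stratification of
a driver variable explains the spatial variance of a response through the
q-statistic

    q = 1 - SSW / SST,

where SSW is the within-stratum and SST the total sum of squares (the
sum-of-squares form is algebraically identical to the population-variance
weighting 1 - sum(N_h sigma_h^2) / (N sigma^2)).  q lies in [0, 1]; q = 1
means the strata explain the response perfectly.

For continuous drivers the stratification is not given: the
optimal-parameter variant scans five discretization methods (equal
interval, natural breaks, quantile, geometric interval, standard
deviation) across a range of class counts (default 5-10) and keeps the
combination maximizing q.  Interaction detection overlays two
stratifications (cartesian product) and classifies the joint q against
the marginals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Dict, FrozenSet, Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import DegenerateLayerError
from .raster_core import RasterGrid, ensure_aligned

#: discretization methods in scan order (used for tie-breaking)
METHODS = ("equal_interval", "natural_breaks", "quantile", "geometric",
           "std_dev")

INTERACTION_CATEGORIES = ("nonlinear weaken", "single-factor weaken",
                          "bi-factor enhance", "independent",
                          "nonlinear enhance")


@dataclass
class SampleTable:
    """Response and driver values at regular-grid sample points.

    ``factors`` maps names to float vectors aligned with ``y``; NaN marks a
    missing driver value (rows are dropped listwise per analysis pair).
    Categorical drivers store integer category codes as floats.
    """

    y: np.ndarray
    factors: Dict[str, np.ndarray]
    categorical: FrozenSet[str] = frozenset()
    coords: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        for name, vec in self.factors.items():
            vec = np.asarray(vec, dtype=float)
            if vec.shape != self.y.shape:
                raise ValueError(f"factor {name!r} length mismatch")
            self.factors[name] = vec
        self.categorical = frozenset(self.categorical)

    @property
    def n(self) -> int:
        return self.y.size


@dataclass
class Discretization:
    """One stratification of a continuous driver.

    ``breaks`` are ascending interior cut points (len = k - 1 after
    degenerate-bin merging); ``labels`` assigns each sample a stratum index
    (-1 for non-finite inputs).  Bins are half-open [b_{i-1}, b_i) with the
    top bin closed.
    """

    method: str
    k: int
    breaks: np.ndarray
    labels: np.ndarray
    q: Optional[float] = None
    scan: Optional[pd.DataFrame] = None


def sample_grid(response: RasterGrid, factors: Dict[str, RasterGrid],
                spacing: int = 1,
                categorical: Iterable[str] = ()) -> SampleTable:
    """Sample every ``spacing``-th cell (both axes) of aligned rasters.

    Cells where the response is masked are dropped; masked factor cells
    become NaN in the table.
    """
    if spacing < 1:
        raise ValueError(f"spacing must be >= 1, got {spacing}")
    ensure_aligned([response] + list(factors.values()))
    rows, cols = response.shape
    rr, cc = np.meshgrid(np.arange(0, rows, spacing),
                         np.arange(0, cols, spacing), indexing="ij")
    rr, cc = rr.ravel(), cc.ravel()
    keep = response.valid[rr, cc]
    rr, cc = rr[keep], cc[keep]
    if rr.size == 0:
        raise DegenerateLayerError("no valid sample points")
    y = response.values[rr, cc]
    fvals = {}
    for name, g in factors.items():
        v = np.where(g.valid[rr, cc], g.values[rr, cc], np.nan)
        fvals[name] = v
    return SampleTable(y=y, factors=fvals,
                       categorical=frozenset(categorical),
                       coords=np.column_stack([rr, cc]))


def q_statistic(y: np.ndarray, strata: np.ndarray) -> float:
    """q = 1 - SSW/SST of a response under a stratification.

    Single-sample strata contribute zero to SSW.  Raises on zero total
    variance.
    """
    y = np.asarray(y, dtype=float)
    strata = np.asarray(strata)
    if y.size != strata.size:
        raise ValueError("y and strata length mismatch")
    if y.size < 2:
        raise DegenerateLayerError("need >= 2 samples")
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst <= 0:
        raise DegenerateLayerError("zero total sum of squares")
    _, inv = np.unique(strata, return_inverse=True)
    cnt = np.bincount(inv)
    s1 = np.bincount(inv, weights=y)
    s2 = np.bincount(inv, weights=y * y)
    ssw = float(np.sum(s2 - s1 * s1 / cnt))
    return float(np.clip(1.0 - ssw / sst, 0.0, 1.0))


def _merge_breaks(breaks: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Clamp interior breaks to the open data range and drop duplicates."""
    b = np.asarray(breaks, dtype=float)
    b = b[(b > lo) & (b <= hi)]
    return np.unique(b)


def _labels_from_breaks(x: np.ndarray, breaks: np.ndarray) -> np.ndarray:
    """Half-open bins [b_{i-1}, b_i), top bin closed; -1 for non-finite."""
    labels = np.full(x.shape, -1, dtype=np.int64)
    finite = np.isfinite(x)
    labels[finite] = np.searchsorted(breaks, x[finite], side="right")
    return labels


def _jenks_all(x_sorted: np.ndarray, kmax: int) -> Dict[int, np.ndarray]:
    """Fisher-Jenks dynamic program: optimal contiguous partitions.

    Returns, for every class count 1..kmax, the ascending interior break
    values minimizing the within-class sum of squares; exact for the given
    (sorted) data.  O(kmax * n^2) time, O(kmax * n) memory.
    """
    n = x_sorted.size
    kmax = min(kmax, n)
    s1 = np.concatenate([[0.0], np.cumsum(x_sorted)])
    s2 = np.concatenate([[0.0], np.cumsum(x_sorted ** 2)])

    def sse(a: np.ndarray, b: int) -> np.ndarray:
        # within-class SSE of x[a..b] inclusive, vectorized over a
        cnt = b - a + 1
        tot = s1[b + 1] - s1[a]
        return (s2[b + 1] - s2[a]) - tot * tot / cnt

    back = np.zeros((kmax + 1, n), dtype=np.int64)
    results: Dict[int, np.ndarray] = {1: np.array([])}
    # prev[i] = optimal SSW of x[0..i] with the previous class count
    prev = s2[1:] - s1[1:] ** 2 / np.arange(1, n + 1)
    for j in range(2, kmax + 1):
        cur = np.full(n, np.inf)
        for i in range(j - 1, n):
            ms = np.arange(j - 1, i + 1)  # start index of the last class
            cand = prev[ms - 1] + sse(ms, i)
            best = int(np.argmin(cand))
            cur[i] = cand[best]
            back[j, i] = ms[best]
        prev = cur
        # backtrack the split points for the full series
        starts = []
        i = n - 1
        for jj in range(j, 1, -1):
            m = back[jj, i]
            starts.append(m)
            i = m - 1
        starts = np.array(sorted(starts))
        results[j] = x_sorted[starts]
    return results


def _jenks_breaks(x: np.ndarray, k: int, max_exact: int = 10000,
                  seed: int = 0) -> np.ndarray:
    xs = np.sort(x)
    if xs.size > max_exact:
        rng = np.random.default_rng(seed)
        xs = np.sort(rng.choice(xs, size=max_exact, replace=False))
    return _jenks_all(xs, k)[k]


def discretize(x: np.ndarray, method: str, k: int, *,
               geometric_g: float = 2.0, std_step: float = 0.5,
               jenks_max_exact: int = 10000,
               jenks_seed: int = 0) -> Discretization:
    """Stratify a continuous vector with one of the five scan methods.

    Breaks: equal_interval at min + i*(max-min)/k; quantile at i/k
    empirical quantiles (type-7); natural_breaks by exact Fisher-Jenks DP
    (deterministic subsample above ``jenks_max_exact`` points); geometric
    at min + (max-min)(g^i - 1)/(g^k - 1); std_dev at mean + f*s*(i - k/2)
    clamped to the data range.  Duplicate breaks are merged and the
    realized class count reported.
    """
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    if method not in METHODS:
        raise ValueError(f"unknown discretization method: {method!r}")
    x = np.asarray(x, dtype=float)
    finite = x[np.isfinite(x)]
    if finite.size < 2:
        raise DegenerateLayerError("fewer than 2 finite values")
    lo, hi = float(finite.min()), float(finite.max())
    distinct = np.unique(finite).size
    if distinct < k:
        warnings.warn(f"{method}: only {distinct} distinct values; "
                      f"reducing k from {k}", stacklevel=2)
        k = max(2, distinct)
    if method == "equal_interval":
        breaks = lo + np.arange(1, k) * (hi - lo) / k
    elif method == "quantile":
        breaks = np.quantile(finite, np.arange(1, k) / k)
    elif method == "natural_breaks":
        breaks = _jenks_breaks(finite, k, jenks_max_exact, jenks_seed)
    elif method == "geometric":
        g = geometric_g
        i = np.arange(1, k)
        breaks = lo + (hi - lo) * (g ** i - 1.0) / (g ** k - 1.0)
    else:  # std_dev
        mean, sd = finite.mean(), finite.std()
        i = np.arange(1, k)
        breaks = mean + std_step * sd * (i - k / 2.0)
    breaks = _merge_breaks(breaks, lo, hi)
    labels = _labels_from_breaks(x, breaks)
    return Discretization(method=method, k=len(breaks) + 1,
                          breaks=breaks, labels=labels)


def optimal_discretization(
    y: np.ndarray, x: np.ndarray,
    methods: Sequence[str] = METHODS,
    k_range: Iterable[int] = range(5, 11),
    jenks_max_exact: int = 10000,
    jenks_seed: int = 0,
) -> Discretization:
    """Scan (method, k) pairs, return the stratification maximizing q.

    Ties go to the smaller k, then to the earlier method in scan order.
    The full diagnostic scan (one q per combination) is attached as
    ``.scan``.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    pair = np.isfinite(y) & np.isfinite(x)
    if pair.sum() < 2:
        raise DegenerateLayerError("fewer than 2 complete (y, x) pairs")
    yv, xv = y[pair], x[pair]
    k_list = sorted(set(int(k) for k in k_range))
    jenks_cache = None
    if "natural_breaks" in methods:
        xs = np.sort(xv)
        if xs.size > jenks_max_exact:
            rng = np.random.default_rng(jenks_seed)
            xs = np.sort(rng.choice(xs, size=jenks_max_exact, replace=False))
        kmax = min(max(k_list), np.unique(xs).size)
        jenks_cache = _jenks_all(xs, kmax)

    best: Optional[Discretization] = None
    rows = []
    for k in k_list:
        for method in methods:
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    if method == "natural_breaks" and jenks_cache is not None:
                        kk = min(k, max(jenks_cache))
                        breaks = _merge_breaks(jenks_cache[kk],
                                               float(xs[0]), float(xs[-1]))
                        disc = Discretization(
                            method=method, k=len(breaks) + 1, breaks=breaks,
                            labels=_labels_from_breaks(x, breaks))
                    else:
                        disc = discretize(xv, method, k,
                                          jenks_max_exact=jenks_max_exact,
                                          jenks_seed=jenks_seed)
                        disc.labels = _labels_from_breaks(x, disc.breaks)
                qv = q_statistic(yv, disc.labels[pair])
            except DegenerateLayerError:
                continue
            disc.q = qv
            rows.append({"method": method, "k_requested": k,
                         "k_realized": disc.k, "q": qv})
            if best is None or qv > best.q:
                best = disc
    if best is None:
        raise DegenerateLayerError("all (method, k) combinations degenerate")
    best.scan = pd.DataFrame(rows)
    return best


def _categorical_labels(x: np.ndarray) -> np.ndarray:
    labels = np.full(x.shape, -1, dtype=np.int64)
    finite = np.isfinite(x)
    _, inv = np.unique(x[finite], return_inverse=True)
    labels[finite] = inv
    return labels


def _permutation_p(y: np.ndarray, labels: np.ndarray, q_obs: float,
                   n_perm: int, rng: np.random.Generator) -> float:
    """Seeded permutation p-value: (1 + #{q_perm >= q_obs}) / (1 + B)."""
    hits = 0
    for _ in range(n_perm):
        try:
            if q_statistic(rng.permutation(y), labels) >= q_obs - 1e-12:
                hits += 1
        except DegenerateLayerError:
            hits += 1
    return (1 + hits) / (1 + n_perm)


def _factor_strata(
    sample: SampleTable,
    k_range: Iterable[int] = range(5, 11),
    methods: Sequence[str] = METHODS,
    jenks_max_exact: int = 10000,
    seed: int = 0,
) -> Dict[str, Discretization]:
    """Best stratification per factor (raw categories for categoricals)."""
    out: Dict[str, Discretization] = {}
    for name, x in sample.factors.items():
        finite = np.isfinite(x)
        if np.unique(x[finite]).size < 2:
            out[name] = Discretization(method="degenerate", k=1,
                                       breaks=np.array([]),
                                       labels=np.full(x.shape, -1), q=None)
            continue
        if name in sample.categorical:
            labels = _categorical_labels(x)
            pair = finite & np.isfinite(sample.y)
            qv = q_statistic(sample.y[pair], labels[pair])
            out[name] = Discretization(
                method="categorical", k=int(np.unique(x[finite]).size),
                breaks=np.array([]), labels=labels, q=qv)
        else:
            out[name] = optimal_discretization(
                sample.y, x, methods=methods, k_range=k_range,
                jenks_max_exact=jenks_max_exact, jenks_seed=seed)
    return out


def factor_detector(
    sample: SampleTable,
    k_range: Iterable[int] = range(5, 11),
    methods: Sequence[str] = METHODS,
    n_perm: int = 999,
    seed: int = 0,
    jenks_max_exact: int = 10000,
    strata: Optional[Dict[str, Discretization]] = None,
) -> pd.DataFrame:
    """Per-factor q with optimal discretization and permutation p-value.

    Continuous factors are discretized by the optimal (method, k) scan;
    categorical factors use their raw categories.  The p-value permutes y
    with strata fixed.  Table sorted by q descending; factors with a
    single distinct value are reported with missing q.
    """
    if not sample.factors:
        raise ValueError("SampleTable has no factors")
    if strata is None:
        strata = _factor_strata(sample, k_range, methods, jenks_max_exact,
                                seed)
    rng = np.random.default_rng(seed)
    rows = []
    for name, disc in strata.items():
        if disc.q is None:
            rows.append({"factor": name, "method": disc.method, "k": disc.k,
                         "q": np.nan, "p_value": np.nan})
            continue
        pair = np.isfinite(sample.y) & (disc.labels >= 0) & \
            np.isfinite(sample.factors[name])
        p = _permutation_p(sample.y[pair], disc.labels[pair], disc.q,
                           n_perm, rng)
        rows.append({"factor": name, "method": disc.method, "k": disc.k,
                     "q": disc.q, "p_value": p})
    return pd.DataFrame(rows).sort_values(
        "q", ascending=False, na_position="last").reset_index(drop=True)


def interaction_q(y: np.ndarray, labels_i: np.ndarray,
                  labels_j: np.ndarray) -> float:
    """q of the cartesian-product stratification of two label vectors."""
    y = np.asarray(y, dtype=float)
    li = np.asarray(labels_i, dtype=np.int64)
    lj = np.asarray(labels_j, dtype=np.int64)
    valid = np.isfinite(y) & (li >= 0) & (lj >= 0)
    if valid.sum() < 2:
        raise DegenerateLayerError("fewer than 2 complete samples")
    combo = li[valid] * (lj.max() + 1) + lj[valid]
    if np.unique(combo).size < 2:
        raise DegenerateLayerError("overlay leaves < 2 nonempty strata")
    return q_statistic(y[valid], combo)


def classify_interaction(q_i: float, q_j: float, q_ij: float,
                         tol: float = 1e-9) -> str:
    """Interaction category of a pair given marginal and overlay q."""
    lo, hi = min(q_i, q_j), max(q_i, q_j)
    if abs(q_ij - (q_i + q_j)) <= tol:
        return "independent"
    if q_ij < lo:
        return "nonlinear weaken"
    if q_ij < hi:
        return "single-factor weaken"
    if q_ij > q_i + q_j:
        return "nonlinear enhance"
    return "bi-factor enhance"  # hi <= q_ij <= q_i + q_j (boundary incl.)


def interaction_detector(sample: SampleTable, factor_i: str, factor_j: str,
                         strata: Dict[str, Discretization]
                         ) -> Tuple[float, str]:
    """Overlay q and category for one factor pair."""
    di, dj = strata[factor_i], strata[factor_j]
    if di.q is None or dj.q is None:
        raise DegenerateLayerError(
            f"degenerate factor in pair ({factor_i}, {factor_j})")
    q_ij = interaction_q(sample.y, di.labels, dj.labels)
    return q_ij, classify_interaction(di.q, dj.q, q_ij)


@dataclass
class OpgdResult:
    """Factor table, pairwise interactions and per-factor stratifications."""

    factor_q: pd.DataFrame
    interaction_q: pd.DataFrame
    discretizations: Dict[str, Discretization] = field(default_factory=dict)


def run_opgd(
    sample: SampleTable,
    k_range: Iterable[int] = range(5, 11),
    methods: Sequence[str] = METHODS,
    n_perm: int = 999,
    seed: int = 0,
    jenks_max_exact: int = 10000,
) -> OpgdResult:
    """Full detector run: optimal discretization, factor q, interactions."""
    strata = _factor_strata(sample, k_range, methods, jenks_max_exact, seed)
    factor_q = factor_detector(sample, k_range, methods, n_perm, seed,
                               jenks_max_exact, strata=strata)
    rows = []
    usable = [n for n, d in strata.items() if d.q is not None]
    for fi, fj in combinations(usable, 2):
        try:
            q_ij, cat = interaction_detector(sample, fi, fj, strata)
        except DegenerateLayerError:
            continue
        rows.append({"factor_i": fi, "factor_j": fj,
                     "q_i": strata[fi].q, "q_j": strata[fj].q,
                     "q_ij": q_ij, "category": cat})
    inter = pd.DataFrame(rows)
    return OpgdResult(factor_q=factor_q, interaction_q=inter,
                      discretizations=strata)
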