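"""Scalar quantization of forcing variables: PMF estimation, Lloyd-Max and
fixed-binning quantizer design, and application to time series.

The Lloyd (Lloyd-Max) algorithm alternates two optimality conditions until the
decision thresholds stop moving:

* each representation point ``x_hat_j`` is the conditional mean of the
  probability mass inside its interval ``alpha_j = (T_{j-1}, T_j]``;
* each interior threshold ``T_j`` is the midpoint of the two adjacent
  representation points.

Expected squared error (the distortion) is non-increasing across iterations,
so the iteration converges to a local minimum of the mean-squared distortion;
a multi-restart option guards against poor local minima.  The iteration runs
on a discrete PMF (histogram bin centres weighted by mass); a sample-based
mode treats each observation as a support point of weight 1/n.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .forcing import ForcingSeries, _Series

__all__ = [
    "Histogram",
    "Quantizer",
    "QuantizedSeries",
    "normal_reference_width",
    "estimate_pmf",
    "lloyd_fit",
    "lloyd_fit_samples",
    "fixed_binning_fit",
    "apply_quantizer",
    "quantizer_distortion",
]


def normal_reference_width(stdev: float, n: int) -> float:
    """Normal-reference-rule histogram bin width, ``3.5 * sigma * n**(-1/3)``.

    Returned unrounded; presentation rounding (1 decimal by default) is a
    display concern applied only when building default histograms.
    """
    if stdev <= 0:
        raise ValueError("stdev must be positive (constant series has no width)")
    if n < 2:
        raise ValueError("need at least two observations")
    return 3.5 * float(stdev) * float(n) ** (-1.0 / 3.0)


@dataclass(frozen=True)
class Histogram:
    """Binned probability estimate of a variable.

    ``edges`` has ``n_bins + 1`` entries; bin ``i`` covers
    ``[edges[i], edges[i+1])`` with the final bin closed on the right.
    """

    edges: np.ndarray
    counts: np.ndarray

    def __post_init__(self):
        edges = np.asarray(self.edges, float)
        counts = np.asarray(self.counts, float)
        if len(edges) != len(counts) + 1:
            raise ValueError("edges must have one more entry than counts")
        if not np.all(np.diff(edges) > 0):
            raise ValueError("edges must be strictly increasing")
        if counts.min() < 0 or counts.sum() <= 0:
            raise ValueError("counts must be non-negative with positive total")
        edges.setflags(write=False)
        counts.setflags(write=False)
        object.__setattr__(self, "edges", edges)
        object.__setattr__(self, "counts", counts)

    @property
    def n(self) -> int:
        return int(round(self.counts.sum()))

    @property
    def n_bins(self) -> int:
        return len(self.counts)

    @property
    def bin_width(self) -> float:
        return float(self.edges[1] - self.edges[0])

    @property
    def origin(self) -> float:
        return float(self.edges[0])

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    @property
    def masses(self) -> np.ndarray:
        """Per-bin probability mass ``p_i = c_i / n`` (sums to 1)."""
        return self.counts / self.counts.sum()

    @property
    def density(self) -> np.ndarray:
        """Estimated density ``f_hat = c_i / (n * delta)``."""
        return self.masses / self.bin_width

    @property
    def mean(self) -> float:
        return float(self.masses @ self.centers)

    @property
    def variance(self) -> float:
        c = self.centers - self.mean
        return float(self.masses @ (c * c))

    def assign(self, x: np.ndarray) -> np.ndarray:
        """Bin index per value, clipped to the outer bins."""
        idx = np.searchsorted(self.edges[1:-1], x, side="right")
        return np.clip(idx, 0, self.n_bins - 1)


def estimate_pmf(
    series: ForcingSeries | np.ndarray,
    bin_width: float,
    origin: float | str = "auto",
    mask: np.ndarray | None = None,
) -> Histogram:
    """Histogram/PMF of a series by bin counting.

    Bins are ``[x0 + i*delta, x0 + (i+1)*delta)`` anchored at ``origin``
    (``"auto"`` anchors the first edge at the data minimum); enough bins are
    laid down to cover the masked data range.  Missing values are excluded.
    """
    values = series.values if isinstance(series, _Series) else np.asarray(series, float)
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    keep = ~np.isnan(values)
    if mask is not None:
        keep &= np.asarray(mask, bool)
    data = values[keep]
    if data.size < 2:
        raise ValueError("need at least two finite values after masking")
    lo, hi = float(data.min()), float(data.max())
    if origin == "auto":
        first = lo
    else:
        first = float(origin) + np.floor((lo - float(origin)) / bin_width) * bin_width
        if first > lo:  # numeric guard
            first -= bin_width
    n_bins = max(int(np.ceil((hi - first) / bin_width)), 1)
    if first + n_bins * bin_width <= hi:
        n_bins += 1
    edges = first + bin_width * np.arange(n_bins + 1)
    counts, _ = np.histogram(data, bins=edges)
    return Histogram(edges, counts)


@dataclass(frozen=True)
class Quantizer:
    """An N-level scalar quantizer.

    ``thresholds`` holds ``T_0..T_N`` (``T_0 = Xmin``, ``T_N = Xmax``);
    ``points`` the representation points ``x_hat_1..x_hat_N``.  Values map to
    half-open intervals ``alpha_j = (T_{j-1}, T_j]`` with the first interval
    closed at the global minimum; out-of-range values clamp to the end
    intervals.
    """

    thresholds: np.ndarray
    points: np.ndarray
    method: str = "lloyd"
    distortion: float = float("nan")
    n_iter: int = 0
    converged: bool = True
    degenerate: bool = False
    trace: tuple = field(default_factory=tuple)

    def __post_init__(self):
        thr = np.asarray(self.thresholds, float)
        pts = np.asarray(self.points, float)
        if len(thr) != len(pts) + 1:
            raise ValueError("need N+1 thresholds for N representation points")
        if len(pts) >= 1 and not np.all(np.diff(thr) > 0):
            raise ValueError("thresholds must be strictly increasing")
        if len(pts) > 1 and not np.all(np.diff(pts) > 0):
            raise ValueError("representation points must be strictly increasing")
        thr.setflags(write=False)
        pts.setflags(write=False)
        object.__setattr__(self, "thresholds", thr)
        object.__setattr__(self, "points", pts)

    @property
    def n_levels(self) -> int:
        return len(self.points)

    def assign(self, x: np.ndarray) -> np.ndarray:
        """Interval index (0-based) per value; clamps outside [T0, TN]."""
        x = np.asarray(x, float)
        return np.searchsorted(self.thresholds[1:-1], x, side="left")

    def quantize(self, x: np.ndarray) -> np.ndarray:
        """Map each value to the representation point of its interval."""
        return self.points[self.assign(x)]

    def summary(self) -> str:
        lines = [
            f"{self.method} quantizer, N={self.n_levels}"
            + ("" if np.isnan(self.distortion) else f", distortion={self.distortion:.6g}"),
            "thresholds: " + np.array2string(self.thresholds, precision=4),
            "points:     " + np.array2string(self.points, precision=4),
        ]
        if self.method == "lloyd":
            lines.append(
                f"iterations={self.n_iter} converged={self.converged}"
                + (" DEGENERATE" if self.degenerate else "")
            )
        return "\n".join(lines)


def _weighted_quantile_thresholds(x: np.ndarray, p: np.ndarray, n_levels: int) -> np.ndarray:
    """Equiprobable interior thresholds from a discrete PMF."""
    cum = np.cumsum(p)
    q = np.arange(1, n_levels) / n_levels
    thr = np.interp(q, cum, x)
    # enforce strict interior ordering; degenerate pmfs fall back to linspace
    if np.any(np.diff(thr) <= 0) or thr[0] <= x[0] or thr[-1] >= x[-1]:
        thr = x[0] + (x[-1] - x[0]) * q
    return thr


def _lloyd_iterate(x, p, interior, tol_abs, max_iter):
    """Core Lloyd iteration on support points ``x`` with masses ``p``."""
    n_levels = len(interior) + 1
    trace: list[float] = []
    converged = False
    empty_seen = np.zeros(n_levels, bool)
    points = None
    it = 0
    for it in range(1, max_iter + 1):
        full = np.concatenate(([x[0]], interior, [x[-1]]))
        idx = np.searchsorted(interior, x, side="left")
        points = np.empty(n_levels)
        empty_seen[:] = False
        for j in range(n_levels):
            sel = idx == j
            mass = p[sel].sum()
            if mass > 0:
                points[j] = (p[sel] @ x[sel]) / mass
            else:  # empty interval: park the point at the interval midpoint
                points[j] = 0.5 * (full[j] + full[j + 1])
                empty_seen[j] = True
        trace.append(float(p @ (x - points[idx]) ** 2))
        new_interior = 0.5 * (points[:-1] + points[1:])
        delta = np.max(np.abs(new_interior - interior)) if n_levels > 1 else 0.0
        interior = new_interior
        if delta < tol_abs:
            converged = True
            break
    return interior, points, trace, it, converged, bool(empty_seen.any())


def _fit_discrete(x, p, n_levels, interior0, tol, max_iter):
    tol_abs = tol * (x[-1] - x[0]) if len(x) > 1 else tol
    interior, points, trace, it, conv, degen = _lloyd_iterate(
        x, p, np.asarray(interior0, float), tol_abs, max_iter
    )
    thresholds = np.concatenate(([x[0]], interior, [x[-1]]))
    return Quantizer(
        thresholds,
        points,
        method="lloyd",
        distortion=trace[-1],
        n_iter=it,
        converged=conv,
        degenerate=degen,
        trace=tuple(trace),
    )


def _lloyd_on_support(
    x: np.ndarray,
    p: np.ndarray,
    n_levels: int,
    init,
    tol: float,
    max_iter: int,
    seed,
    restarts: int,
) -> Quantizer:
    if n_levels < 1:
        raise ValueError("need at least one quantization level")
    populated = int((p > 0).sum())
    if n_levels > populated:
        raise ValueError(
            f"insufficient support: {n_levels} levels requested but only "
            f"{populated} populated bins"
        )
    if tol <= 0:
        raise ValueError("tol must be positive")
    if n_levels == 1:
        mean = float(p @ x)
        var = float(p @ (x - mean) ** 2)
        lo = x[0] if len(x) > 1 else x[0] - 0.5
        hi = x[-1] if len(x) > 1 and x[-1] > x[0] else x[0] + 0.5
        return Quantizer(np.array([lo, hi]), np.array([mean]), method="lloyd",
                         distortion=var, n_iter=1, converged=True, trace=(var,))

    inits: list[np.ndarray] = []
    if isinstance(init, str):
        if init == "quantile":
            # two deterministic starts: equiprobable and equal-width thresholds.
            # Descending from the equal-width start guarantees the converged
            # distortion never exceeds the fixed-binning baseline.
            inits.append(_weighted_quantile_thresholds(x, p, n_levels))
            inits.append(x[0] + (x[-1] - x[0]) * np.arange(1, n_levels) / n_levels)
        elif init == "random":
            pass  # drawn below
        else:
            raise ValueError(f"unknown init {init!r}")
    else:
        explicit = np.asarray(init, float)
        if len(explicit) != n_levels - 1:
            raise ValueError("explicit init needs N-1 interior thresholds")
        inits.append(explicit)

    all_random = isinstance(init, str) and init == "random"
    n_random = max(restarts, 1) if all_random else max(restarts - len(inits), 0)
    if n_random > 0:
        rng = np.random.default_rng(seed)
        cum = np.cumsum(p)
        for k in range(n_random):
            # alternate plain range-uniform draws with draws mapped through
            # the quantile function, which explores basins where mass lives
            u = np.sort(rng.uniform(0.0, 1.0, size=n_levels - 1))
            if k % 2 == 0:
                draw = np.interp(u, cum, x)
            else:
                draw = x[0] + (x[-1] - x[0]) * u
            if np.any(np.diff(draw) <= 0):
                draw = x[0] + (x[-1] - x[0]) * np.sort(rng.uniform(0, 1, n_levels - 1))
            inits.append(draw)

    best: Quantizer | None = None
    for interior0 in inits:
        q = _fit_discrete(x, p, n_levels, interior0, tol, max_iter)
        if best is None or q.distortion < best.distortion:
            best = q
    assert best is not None
    return best


def lloyd_fit(
    pmf: Histogram,
    n_levels: int,
    init="quantile",
    tol: float = 1e-6,
    max_iter: int = 500,
    seed: int | None = None,
    restarts: int = 1,
) -> Quantizer:
    """Fit an N-level Lloyd-Max quantizer to a discrete PMF.

    Parameters
    ----------
    pmf : Histogram
        Probability estimate; the iteration runs on its bin centres weighted
        by mass.
    n_levels : int
        Number of representation points (N >= 1).
    init : {"quantile", "random"} or array of N-1 interior thresholds
        Initial decision thresholds.  ``"quantile"`` (equiprobable) is the
        deterministic default; ``"random"`` draws from the data range.
    tol : float
        Convergence tolerance as a fraction of the data range: iteration
        stops when ``max |delta T_j| < tol * (Xmax - Xmin)``.
    max_iter : int
        Iteration cap; if hit, the result carries ``converged=False``.
    seed, restarts : optional
        ``restarts > 1`` re-runs from additional seeded random initial
        guesses and keeps the lowest-distortion fit.

    The returned quantizer stores the distortion trace (one entry per
    iteration, non-increasing) and a ``degenerate`` flag if an interval had
    zero mass at convergence.
    """
    q = _lloyd_on_support(pmf.centers, pmf.masses, n_levels, init, tol,
                          max_iter, seed, restarts)
    if isinstance(init, str) and init == "quantile" and n_levels > 1:
        # also descend from the equal-width partition of the histogram range,
        # so the fit dominates a fixed-binning baseline on the same pmf
        edges_init = pmf.edges[0] + (pmf.edges[-1] - pmf.edges[0]) \
            * np.arange(1, n_levels) / n_levels
        alt = _lloyd_on_support(pmf.centers, pmf.masses, n_levels,
                                edges_init, tol, max_iter, seed, 1)
        if alt.distortion < q.distortion:
            q = alt
    return q


def lloyd_fit_samples(
    values: np.ndarray,
    n_levels: int,
    init="quantile",
    tol: float = 1e-6,
    max_iter: int = 500,
    seed: int | None = None,
    restarts: int = 1,
) -> Quantizer:
    """Sample-based Lloyd fit: every observation is a support point of weight 1/n."""
    values = np.asarray(values, float)
    values = values[~np.isnan(values)]
    if values.size < 2:
        raise ValueError("need at least two finite values")
    x, counts = np.unique(values, return_counts=True)
    return _lloyd_on_support(x, counts / counts.sum(), n_levels, init, tol,
                             max_iter, seed, restarts)


def fixed_binning_fit(xmin: float, xmax: float, n_levels: int) -> Quantizer:
    """Equal-width baseline quantizer with bin-centre representation points."""
    if xmax <= xmin:
        raise ValueError("xmax must exceed xmin")
    if n_levels < 1:
        raise ValueError("need at least one level")
    thresholds = np.linspace(xmin, xmax, n_levels + 1)
    points = 0.5 * (thresholds[:-1] + thresholds[1:])
    return Quantizer(thresholds, points, method="fixed")


def quantizer_distortion(q: Quantizer, pmf: Histogram) -> float:
    """Expected squared-error distortion of ``q`` against a PMF."""
    x = pmf.centers
    err = x - q.points[q.assign(x)]
    return float(pmf.masses @ (err * err))


@dataclass(frozen=True)
class QuantizedSeries:
    """A series after quantization, with pass-through for masked-out steps."""

    name: str
    values: np.ndarray       # representation value (or original where passed through)
    levels: np.ndarray       # interval index, -1 where passed through or missing
    quantized: np.ndarray    # bool: True where the quantizer was applied

    def __post_init__(self):
        for arr in ("values", "levels", "quantized"):
            a = getattr(self, arr)
            a.setflags(write=False)


def apply_quantizer(
    series: ForcingSeries,
    q: Quantizer,
    mask: np.ndarray | None = None,
) -> QuantizedSeries:
    """Quantize a series; steps outside ``mask`` (and missing steps) pass through.

    Values in interval ``alpha_j`` map to ``x_hat_j``; values outside
    ``[T0, TN]`` clamp to the nearest end interval.
    """
    values = series.values
    apply_to = ~np.isnan(values)
    if mask is not None:
        apply_to &= np.asarray(mask, bool)
    out = values.copy()
    levels = np.full(len(values), -1, dtype=int)
    idx = q.assign(values[apply_to])
    out[apply_to] = q.points[idx]
    levels[apply_to] = idx
    return QuantizedSeries(series.name, out, levels, apply_to)
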