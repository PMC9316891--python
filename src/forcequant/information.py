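"""Discrete entropy, joint entropy, and the forcing-complexity ratio Cm.

Entropy is Shannon entropy in bits, ``H = -sum p_n log2 p_n``, computed from
category frequencies obtained by discretizing a series either with a fitted
quantizer (categories = its N levels) or with a histogram binning.  The
forcing complexity of a quantized scenario,

    Cm = H(Ta_q, U_q, VPD_q) / H(Ta, U, VPD),

is the joint entropy of the (possibly quantized) forcing variables relative
to the joint entropy of the same variables at full resolution.  Variables a
scenario leaves untouched enter the numerator at full resolution, so Cm = 1
for the full model and Cm -> 0 as every variable collapses to a constant.

The "full resolution" discretization of continuous data is itself a choice;
by default each variable is binned with its normal-reference-rule width
(see :func:`full_resolution_histograms`), and any histogram or bin width can
be substituted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .forcing import ForcingSeries, ForcingSet, _Series
from .quantize import Histogram, Quantizer, estimate_pmf, normal_reference_width

__all__ = [
    "EntropyResult",
    "ComplexityResult",
    "entropy",
    "series_entropy",
    "joint_entropy",
    "complexity_cm",
    "full_resolution_histograms",
]

MET_VARIABLES = ("Ta", "U", "VPD")


@dataclass(frozen=True)
class EntropyResult:
    """Shannon entropy of a discretized variable."""

    H: float                  # bits
    n_bins: int               # declared total number of categories Nd
    n_populated: int
    probabilities: np.ndarray

    @property
    def Hmax(self) -> float:
        """Maximum possible entropy, log2(Nd), attained by a uniform PMF."""
        return float(np.log2(self.n_bins)) if self.n_bins else 0.0


def entropy(masses: Sequence[float], n_bins: int | None = None) -> EntropyResult:
    """Entropy (bits) of a probability mass sequence.

    Zero-mass bins contribute zero by the usual ``0 log 0 = 0`` convention.
    ``n_bins`` declares the total category count used for Hmax; it defaults
    to the length of ``masses``.
    """
    p = np.asarray(masses, float)
    if p.min() < 0:
        raise ValueError("negative probability mass")
    total = p.sum()
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"masses sum to {total}, not 1")
    pos = p[p > 0]
    h = float(-(pos @ np.log2(pos)))
    return EntropyResult(h, n_bins if n_bins is not None else len(p),
                         len(pos), p)


def _categorize(values: np.ndarray, disc) -> tuple[np.ndarray, int]:
    """Category index per finite value, plus the declared category count."""
    if isinstance(disc, Quantizer):
        return disc.assign(values), disc.n_levels
    if isinstance(disc, Histogram):
        return disc.assign(values), disc.n_bins
    if np.isscalar(disc):  # a bin width
        hist = estimate_pmf(values, float(disc))
        return hist.assign(values), hist.n_bins
    raise TypeError(f"cannot discretize with {type(disc).__name__}")


def _finite_values(series, mask=None) -> np.ndarray:
    values = series.values if isinstance(series, _Series) else np.asarray(series, float)
    keep = ~np.isnan(values)
    if mask is not None:
        keep &= np.asarray(mask, bool)
    out = values[keep]
    if out.size == 0:
        raise ValueError("no finite values to discretize")
    return out


def series_entropy(series, disc, mask: np.ndarray | None = None) -> EntropyResult:
    """Entropy of a series under a discretization (Quantizer, Histogram or width)."""
    values = _finite_values(series, mask)
    codes, n_bins = _categorize(values, disc)
    counts = np.bincount(codes, minlength=n_bins).astype(float)
    return entropy(counts / counts.sum(), n_bins=n_bins)


def joint_entropy(
    series_list: Sequence,
    discretizations: Sequence,
    mask: np.ndarray | None = None,
) -> float:
    """Joint entropy (bits) of several aligned series by direct counting.

    Each timestep contributes one tuple of category indices; the entropy of
    the empirical tuple distribution is returned.  Timesteps missing in any
    series are dropped listwise.
    """
    if len(series_list) != len(discretizations):
        raise ValueError("need one discretization per series")
    arrays = [s.values if isinstance(s, _Series) else np.asarray(s, float)
              for s in series_list]
    n = len(arrays[0])
    if any(len(a) != n for a in arrays):
        raise ValueError("series are not aligned on one grid")
    keep = ~np.any(np.isnan(np.vstack(arrays)), axis=0)
    if mask is not None:
        keep &= np.asarray(mask, bool)
    if not keep.any():
        raise ValueError("no jointly finite timesteps")
    codes = np.vstack([
        _categorize(a[keep], d)[0] for a, d in zip(arrays, discretizations)
    ])
    _, counts = np.unique(codes, axis=1, return_counts=True)
    p = counts / counts.sum()
    return float(-(p @ np.log2(p)))


def full_resolution_histograms(
    fset: ForcingSet,
    variables: Sequence[str] = MET_VARIABLES,
    widths: Mapping[str, float] | None = None,
    round_decimals: int | None = 1,
) -> dict[str, Histogram]:
    """Per-variable full-resolution histograms for the Cm denominator.

    Bin widths default to the normal reference rule on each variable, with a
    1-decimal presentation rounding (pass ``round_decimals=None`` for the
    unrounded widths, or supply ``widths`` explicitly).
    """
    out: dict[str, Histogram] = {}
    for name in variables:
        values = _finite_values(fset[name])
        if widths and name in widths:
            w = widths[name]
        else:
            w = normal_reference_width(values.std(ddof=0), values.size)
            if round_decimals is not None:
                w = round(w, round_decimals) or w  # keep unrounded if rounds to 0
        out[name] = estimate_pmf(values, w)
    return out


@dataclass(frozen=True)
class ComplexityResult:
    """Forcing complexity Cm = H(quantized set) / H(full-resolution set)."""

    cm: float
    h_quantized: float        # bits
    h_full: float             # bits
    levels: dict              # variable -> N, or "full"

    def __post_init__(self):
        if not -1e-9 <= self.cm <= 1.0 + 1e-9:
            raise ValueError(f"Cm={self.cm} outside [0, 1]")


def complexity_cm(
    fset: ForcingSet,
    quantizers: Mapping[str, Quantizer],
    variables: Sequence[str] = MET_VARIABLES,
    full_discs: Mapping[str, Histogram] | None = None,
) -> ComplexityResult:
    """Forcing complexity of a quantization scenario.

    ``quantizers`` maps a subset of ``variables`` to fitted quantizers; the
    rest enter the numerator at full resolution.  The denominator always uses
    the full-resolution discretization of every variable.
    """
    if full_discs is None:
        full_discs = full_resolution_histograms(fset, variables)
    series = [fset[v] for v in variables]
    full = [full_discs[v] for v in variables]
    h_full = joint_entropy(series, full)
    if h_full <= 0:
        raise ValueError("degenerate forcing: full-resolution joint entropy is zero")
    num_discs = [quantizers.get(v, full_discs[v]) for v in variables]
    h_q = joint_entropy(series, num_discs)
    levels = {v: (quantizers[v].n_levels if v in quantizers else "full")
              for v in variables}
    return ComplexityResult(min(h_q / h_full, 1.0), h_q, h_full, levels)
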