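"""Independent oracles used by the tests.

These deliberately avoid the package's own code paths: the optimal-partition
oracle enumerates every contiguous partition of a discrete PMF by brute
force, which is exact for small support sets and checks the Lloyd iteration
from the outside.
"""

from __future__ import annotations

import itertools

import numpy as np


def segment_sse(x: np.ndarray, p: np.ndarray) -> float:
    """Weighted sum of squared errors of one segment about its weighted mean."""
    mass = p.sum()
    if mass == 0:
        return 0.0
    mean = (p @ x) / mass
    return float(p @ (x - mean) ** 2)


def optimal_partition_distortion(x, p, n_levels: int) -> float:
    """Globally minimal expected squared-error distortion of an N-level
    scalar quantizer on a discrete PMF, by exhaustive search over all
    contiguous partitions of the support points."""
    x = np.asarray(x, float)
    p = np.asarray(p, float)
    order = np.argsort(x)
    x, p = x[order], p[order]
    k = len(x)
    if n_levels >= k:
        return 0.0
    best = np.inf
    for cuts in itertools.combinations(range(1, k), n_levels - 1):
        bounds = (0, *cuts, k)
        d = sum(segment_sse(x[a:b], p[a:b]) for a, b in zip(bounds[:-1], bounds[1:]))
        best = min(best, d)
    return best


def shannon_entropy_bits(counts) -> float:
    """Plain entropy of a count vector, written independently of the package."""
    c = np.asarray(counts, float)
    p = c[c > 0] / c.sum()
    return float(-np.sum(p * np.log2(p)))
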