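"""Percentile benchmarks, threshold proportions, and shape summaries.

Field-specific effect-size guidelines are read off the empirical
distribution of published effects: the 25th, 50th, and 75th percentiles
of the observed magnitudes are labeled small, medium, and large.  The
quantile convention is linear interpolation of order statistics
(h = (N-1)p + 1; R type 7, numpy's default), which the benchmark values
depend on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .corpus import Corpus

__all__ = [
    "BenchmarkTable",
    "quantile",
    "benchmark",
    "proportion_at_least",
    "moments",
    "round_guideline",
    "histogram_prep",
    "density_prep",
    "DEFAULT_GRID",
    "COHEN_GUIDELINES",
]

DEFAULT_GRID = tuple(range(5, 100, 5))
# Cohen's conventional small/medium/large thresholds, for comparison rows.
COHEN_GUIDELINES = {"r": (0.10, 0.30, 0.50), "g": (0.20, 0.50, 0.80)}
_LABELED = {25: "small", 50: "medium", 75: "large"}


@dataclass(frozen=True)
class BenchmarkTable:
    """Percentile -> effect-magnitude mapping for one metric and subgroup."""

    metric: str
    subgroup: str
    percentiles: tuple[float, ...]
    values: tuple[float, ...]
    n_records: int

    def __post_init__(self):
        ps = self.percentiles
        if any(not 0 < p < 100 for p in ps):
            raise ValueError("percentiles must lie strictly inside (0, 100)")
        if any(b <= a for a, b in zip(ps, ps[1:])):
            raise ValueError("percentiles must be strictly increasing")
        if any(b < a - 1e-12 for a, b in zip(self.values, self.values[1:])):
            raise ValueError("effect magnitudes must be nondecreasing in percentile")

    @property
    def labels(self) -> dict[str, float]:
        """small/medium/large values where the grid includes 25/50/75."""
        out = {}
        for p, v in zip(self.percentiles, self.values):
            if p in _LABELED:
                out[_LABELED[p]] = v
        return out

    def quartiles(self) -> tuple[float, float, float]:
        lab = self.labels
        try:
            return (lab["small"], lab["medium"], lab["large"])
        except KeyError:
            raise ValueError("grid does not include the 25/50/75 percentiles")


def quantile(values, p: float) -> float:
    """Linear-interpolation quantile of a collection at proportion p in [0,1]."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot take a quantile of an empty collection")
    if not 0 <= p <= 1:
        raise ValueError(f"p must lie in [0, 1], got {p}")
    return float(np.quantile(arr, p, method="linear"))


def benchmark(
    corpus: Corpus,
    metric: str,
    subgroup: str = "all",
    grid=DEFAULT_GRID,
) -> BenchmarkTable:
    """Percentile benchmarks of one metric over an optional category subgroup."""
    vals = corpus.values(metric=metric, subgroup=subgroup)
    if not vals:
        raise ValueError(f"no records with metric={metric!r} in subgroup={subgroup!r}")
    grid = tuple(float(p) for p in grid)
    qs = tuple(quantile(vals, p / 100.0) for p in grid)
    return BenchmarkTable(
        metric=metric, subgroup=subgroup, percentiles=grid, values=qs, n_records=len(vals)
    )


def proportion_at_least(
    corpus: Corpus, metric: str, threshold: float, subgroup: str = "all"
) -> float:
    """Fraction of records of the metric whose magnitude is >= threshold."""
    vals = corpus.values(metric=metric, subgroup=subgroup)
    if not vals:
        raise ValueError(f"no records with metric={metric!r} in subgroup={subgroup!r}")
    return sum(1 for v in vals if v >= threshold) / len(vals)


def moments(values) -> dict[str, float]:
    """Moment-based skewness and kurtosis of a sample.

    Returns skewness m3/m2^(3/2) and kurtosis in both conventions —
    raw m4/m2^2 and excess m4/m2^2 - 3 — since reported kurtosis values
    in the literature rarely state which one they use.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 3:
        raise ValueError("need at least 3 values for shape moments")
    m2 = np.mean((arr - arr.mean()) ** 2)
    if m2 == 0:
        raise ValueError("zero variance: shape moments undefined")
    m3 = np.mean((arr - arr.mean()) ** 3)
    m4 = np.mean((arr - arr.mean()) ** 4)
    raw_kurt = m4 / m2**2
    return {
        "skewness": float(m3 / m2**1.5),
        "kurtosis_raw": float(raw_kurt),
        "kurtosis_excess": float(raw_kurt - 3.0),
    }


def round_guideline(value: float) -> float:
    """Round an effect magnitude to the nearest 0.05, ties rounding up.

    Matches how percentile-derived benchmarks are simplified into
    memorable guideline values (e.g. 0.38 -> 0.40, 0.76 -> 0.75).
    """
    if value < 0:
        raise ValueError(f"guideline rounding expects a magnitude >= 0, got {value}")
    # work in integer twentieths to dodge binary-fraction artifacts
    return math.floor(round(value / 0.05, 9) + 0.5) * 0.05


def histogram_prep(values, bins: int = 30) -> tuple[np.ndarray, np.ndarray]:
    """Bin edges and counts for a histogram of effect magnitudes."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot histogram an empty collection")
    counts, edges = np.histogram(arr, bins=bins)
    return edges, counts


def density_prep(
    values, bandwidth: float | str = "silverman", n_points: int = 512
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian-kernel density curve (grid, density) for plotting.

    ``bandwidth`` is either Silverman's rule (default) or a positive
    scalar factor on the sample standard deviation, as in
    :class:`scipy.stats.gaussian_kde`.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("need at least 2 values for a density estimate")
    if isinstance(bandwidth, (int, float)):
        if bandwidth <= 0:
            raise ValueError(f"bandwidth must be positive, got {bandwidth}")
        kde = stats.gaussian_kde(arr, bw_method=float(bandwidth))
    else:
        kde = stats.gaussian_kde(arr, bw_method=bandwidth)
    pad = 5 * kde.factor * arr.std(ddof=1)
    grid = np.linspace(arr.min() - pad, arr.max() + pad, n_points)
    return grid, kde(grid)
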