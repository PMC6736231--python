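"""Exact power and sample-size computation for the two designs in the corpus.

Group differences use the exact noncentral-t distribution of the two-sample
t statistic: with groups of ``n1`` and ``n2`` and a true standardized mean
difference ``d``, the statistic is noncentral t with ``df = n1 + n2 - 2``
and noncentrality ``delta = d * sqrt(n1*n2/(n1+n2))``.  Two-sided power at
level alpha is

    P(T > t*) + P(T < -t*),   t* = central-t quantile at 1 - alpha/2.

Correlations use the classical Fisher-z approximation to the power of the
t-test of H0: rho = 0 (the computation behind ``pwr.r.test``): the critical
correlation is mapped from the central-t critical value, both it and the
(bias-adjusted) population correlation are moved to the atanh scale, and
the test statistic is treated as normal with standard deviation
``1/sqrt(n-3)``.

Sample-size solvers return the smallest integer n meeting the target power
(ceiling of the continuous root found by bracketing and Brent's method).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from statistics import median

import numpy as np
from scipy import optimize, stats

from .corpus import Corpus

__all__ = [
    "PowerQuery",
    "PowerResult",
    "PowerSummary",
    "power_two_sample_t",
    "solve_n_two_sample",
    "power_correlation",
    "solve_n_correlation",
    "corpus_power_summary",
]

_N_MAX = 10_000_000  # solver bracket cap; beyond this the target is declared unreachable


@dataclass(frozen=True)
class PowerQuery:
    """Inputs of a power or sample-size computation."""

    metric: str  # "r" or "g"
    effect: float
    n1: int | None = None
    n2: int | None = None
    alpha: float = 0.05
    tails: str = "two"
    target_power: float | None = None

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0,1), got {self.alpha}")
        if self.effect < 0:
            raise ValueError(f"effect must be nonnegative, got {self.effect}")
        if self.target_power is not None and not self.alpha < self.target_power < 1:
            raise ValueError(
                f"target power must lie in (alpha, 1), got {self.target_power}"
            )
        if self.tails not in ("two", "one"):
            raise ValueError(f"tails must be 'two' or 'one', got {self.tails!r}")


@dataclass(frozen=True)
class PowerResult:
    """Achieved power together with the test geometry that produced it."""

    power: float
    df: float
    ncp: float
    crit: float


@dataclass(frozen=True)
class PowerSummary:
    """Corpus-level achieved-power summary at a reference effect."""

    n_records: int
    n_powered: int
    fraction_powered: float
    median_n1: float
    median_n2: float | None
    median_total_n: float
    powers: tuple[float, ...]


def _nct_cdf(x: float, df: float, ncp: float) -> float:
    """Noncentral-t CDF, falling back to the asymptotic normal for the
    extreme df/ncp ranges where scipy's series implementation returns NaN."""
    val = float(stats.nct.cdf(x, df, ncp))
    if math.isnan(val):
        sd = math.sqrt(max(1.0 + ncp * ncp / (2.0 * df), 1e-12))
        val = float(stats.norm.cdf((x - ncp) / sd))
    return val


def _check_tails(tails: str) -> None:
    if tails not in ("two", "one"):
        raise ValueError(f"tails must be 'two' or 'one', got {tails!r}")


def power_two_sample_t(
    d: float, n1: int, n2: int, alpha: float = 0.05, tails: str = "two"
) -> PowerResult:
    """Exact noncentral-t power of the independent-samples t-test.

    Handles unequal group sizes; the equal-group case is the special case
    ``delta = d * sqrt(n/2)``.
    """
    _check_tails(tails)
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0,1), got {alpha}")
    if n1 < 2 or n2 < 2:
        raise ValueError(f"both groups need n >= 2, got n1={n1}, n2={n2}")
    df = n1 + n2 - 2
    ncp = d * math.sqrt(n1 * n2 / (n1 + n2))
    if tails == "two":
        crit = stats.t.ppf(1 - alpha / 2, df)
        power = (1 - _nct_cdf(crit, df, ncp)) + _nct_cdf(-crit, df, ncp)
    else:
        crit = stats.t.ppf(1 - alpha, df)
        power = 1 - _nct_cdf(crit, df, ncp)
    return PowerResult(power=float(power), df=float(df), ncp=float(ncp), crit=float(crit))


def power_correlation(
    r: float, n: int, alpha: float = 0.05, tails: str = "two"
) -> PowerResult:
    """Fisher-z approximate power of the test of zero correlation.

    The critical correlation r_c is the value whose t statistic sits at the
    central-t critical point; power is evaluated on the atanh scale where
    the estimator is approximately normal with sd 1/sqrt(n-3) and mean
    atanh(r) + r/(2(n-1)) (the mean-bias adjustment of the z transform).
    """
    _check_tails(tails)
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0,1), got {alpha}")
    if n < 4:
        raise ValueError(f"correlation power requires n >= 4, got {n}")
    if not 0 <= r < 1:
        raise ValueError(f"r must lie in [0, 1), got {r}")
    df = n - 2
    if tails == "two":
        crit = stats.t.ppf(1 - alpha / 2, df)
    else:
        crit = stats.t.ppf(1 - alpha, df)
    r_c = math.sqrt(crit**2 / (crit**2 + df))
    z_c = math.atanh(r_c)
    z_r = math.atanh(r) + r / (2 * (n - 1))
    scale = math.sqrt(n - 3)
    power = stats.norm.cdf((z_r - z_c) * scale)
    if tails == "two":
        power += stats.norm.cdf((-z_r - z_c) * scale)
    return PowerResult(power=float(power), df=float(df), ncp=float(z_r * scale), crit=float(crit))


def _solve_smallest_n(power_at, n_min: int, target_power: float) -> int:
    """Smallest integer n >= n_min with power_at(n) >= target_power.

    Brackets by doubling from n_min (power is monotone in n), runs Brent's
    method on the continuous relaxation, then takes the ceiling and nudges
    across any root-tolerance wobble.
    """
    if power_at(n_min) >= target_power:
        return n_min
    lo, hi = float(n_min), float(n_min) * 2
    while power_at(hi) < target_power:
        lo, hi = hi, hi * 2
        if hi > _N_MAX:
            raise ValueError(
                f"target power {target_power} not reachable with n <= {_N_MAX}"
            )
    root = optimize.brentq(lambda n: power_at(n) - target_power, lo, hi, xtol=1e-8)
    n = math.ceil(root - 1e-9)
    while power_at(n) < target_power:  # guard against ceiling landing short
        n += 1
    while n > n_min and power_at(n - 1) >= target_power:
        n -= 1
    return n


def solve_n_two_sample(
    d: float, target_power: float, alpha: float = 0.05, tails: str = "two"
) -> int:
    """Smallest per-group n for the two-sample t-test to reach target power."""
    if d <= 0:
        raise ValueError(f"effect must be positive, got {d}")
    if not alpha < target_power < 1:
        raise ValueError(f"target power must lie in (alpha, 1), got {target_power}")
    return _solve_smallest_n(
        lambda n: _continuous_power_t(d, float(n), alpha, tails), 2, target_power
    )


def _continuous_power_t(d: float, n: float, alpha: float, tails: str) -> float:
    df = 2 * n - 2
    ncp = d * math.sqrt(n / 2)
    if tails == "two":
        crit = stats.t.ppf(1 - alpha / 2, df)
        return (1 - _nct_cdf(crit, df, ncp)) + _nct_cdf(-crit, df, ncp)
    crit = stats.t.ppf(1 - alpha, df)
    return 1 - _nct_cdf(crit, df, ncp)


def _continuous_power_r(r: float, n: float, alpha: float, tails: str) -> float:
    df = n - 2
    if tails == "two":
        crit = stats.t.ppf(1 - alpha / 2, df)
    else:
        crit = stats.t.ppf(1 - alpha, df)
    r_c = math.sqrt(crit**2 / (crit**2 + df))
    z_c = math.atanh(r_c)
    z_r = math.atanh(r) + r / (2 * (n - 1))
    scale = math.sqrt(n - 3)
    power = stats.norm.cdf((z_r - z_c) * scale)
    if tails == "two":
        power += stats.norm.cdf((-z_r - z_c) * scale)
    return float(power)


def solve_n_correlation(
    r: float, target_power: float, alpha: float = 0.05, tails: str = "two"
) -> int:
    """Smallest total n for the correlation test to reach target power."""
    if r <= 0:
        raise ValueError(f"effect must be positive, got {r}")
    if not alpha < target_power < 1:
        raise ValueError(f"target power must lie in (alpha, 1), got {target_power}")
    return _solve_smallest_n(
        lambda n: _continuous_power_r(r, float(n), alpha, tails), 4, target_power
    )


def achieved_power(record, reference_effect: float, alpha: float = 0.05) -> float:
    """Power of one record's design at a reference population effect."""
    if record.metric == "r":
        return power_correlation(reference_effect, record.n1, alpha).power
    return power_two_sample_t(reference_effect, record.n1, record.n2, alpha).power


def corpus_power_summary(
    corpus: Corpus,
    reference_effect: dict[str, float] | float,
    alpha: float = 0.05,
    metric: str | None = None,
    subgroup: str = "all",
    power_threshold: float = 0.80,
) -> PowerSummary:
    """Achieved power of every record at a per-metric reference effect.

    ``reference_effect`` is either a single magnitude (applied to every
    selected record) or a mapping like ``{"r": .20, "g": .38}``.  Returns
    the fraction of records whose design reaches ``power_threshold`` at the
    reference effect, plus median sample sizes.
    """
    records = corpus.select(metric=metric, subgroup=subgroup)
    if not records:
        raise ValueError("no records match the requested metric/subgroup")
    powers = []
    for rec in records:
        if isinstance(reference_effect, dict):
            eff = reference_effect[rec.metric]
        else:
            eff = float(reference_effect)
        powers.append(achieved_power(rec, eff, alpha))
    n_powered = sum(1 for p in powers if p >= power_threshold)
    n1s = [rec.n1 for rec in records]
    n2s = [rec.n2 for rec in records if rec.n2 is not None]
    totals = [rec.n1 + (rec.n2 or 0) for rec in records]
    return PowerSummary(
        n_records=len(records),
        n_powered=n_powered,
        fraction_powered=n_powered / len(records),
        median_n1=float(median(n1s)),
        median_n2=float(median(n2s)) if n2s else None,
        median_total_n=float(median(totals)),
        powers=tuple(powers),
    )
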