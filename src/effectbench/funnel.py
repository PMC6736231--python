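"""Contour-enhanced funnel geometry: standard errors, p-values, regions.

Each effect is placed in (effect, SE) space and classified by its
normal-theory two-sided p-value into the significance bands familiar from
contour-enhanced funnel plots: white (p >= .10), orange (.05 <= p < .10),
red (.01 <= p < .05), and gray (p < .01).  An excess of points in the
orange/red bands — results hovering just at or past significance — is the
visual signature of inflation bias.

Group-difference effects use the large-sample SE of a standardized mean
difference; correlations are mapped to the Fisher-z scale where the SE is
1/sqrt(n-3).  Boundary p-values (.10/.05/.01 exactly) classify into the
less significant region so the partition is deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .corpus import Corpus, EffectRecord

__all__ = [
    "FunnelPoint",
    "FunnelSummary",
    "REGIONS",
    "CONTOUR_Z",
    "se_of_g",
    "se_of_r_fisher",
    "p_value_z",
    "contour_region",
    "classify_record",
    "funnel_table",
    "funnel_plot_prep",
]

REGIONS = ("white", "orange", "red", "gray")
# standard-normal quantiles of the p = .10 / .05 / .01 two-sided contours
CONTOUR_Z = {0.10: 1.6448536269514722, 0.05: 1.959963984540054, 0.01: 2.5758293035489004}


@dataclass(frozen=True)
class FunnelPoint:
    """One classified effect in funnel coordinates."""

    meta_id: str
    study_id: str
    metric: str
    effect: float  # g, or atanh(r) for correlations
    se: float
    p: float
    region: str


@dataclass(frozen=True)
class FunnelSummary:
    """Counts and percentages per significance region."""

    subgroup: str
    counts: dict[str, int]
    n_classified: int
    n_skipped: int

    @property
    def percentages(self) -> dict[str, float]:
        if self.n_classified == 0:
            return {r: float("nan") for r in REGIONS}
        return {r: 100.0 * self.counts[r] / self.n_classified for r in REGIONS}


def se_of_g(g: float, n1: int, n2: int) -> float:
    """Large-sample standard error of a standardized mean difference."""
    if n1 < 2 or n2 < 2:
        raise ValueError(f"both groups need n >= 2, got n1={n1}, n2={n2}")
    n = n1 + n2
    return math.sqrt((n1 + n2) / (n1 * n2) + g * g / (2 * n))


def se_of_r_fisher(n: int) -> float:
    """Standard error of a correlation on the Fisher-z (atanh) scale."""
    if n < 4:
        raise ValueError(f"Fisher-z SE requires n >= 4, got {n}")
    return 1.0 / math.sqrt(n - 3)


def p_value_z(effect: float, se: float) -> float:
    """Two-sided normal-theory p-value of effect/se."""
    if se <= 0:
        raise ValueError(f"se must be positive, got {se}")
    # floor at the smallest normal double so extreme effects stay in (0, 1]
    return max(float(2.0 * stats.norm.sf(abs(effect) / se)), 2.2250738585072014e-308)


def contour_region(p: float) -> str:
    """Significance band of a p-value; ties go to the less significant band."""
    if not 0 < p <= 1:
        raise ValueError(f"p must lie in (0, 1], got {p}")
    if p < 0.01:
        return "gray"
    if p < 0.05:
        return "red"
    if p < 0.10:
        return "orange"
    return "white"


def classify_record(rec: EffectRecord) -> FunnelPoint | None:
    """Funnel coordinates and region for one record; None if n is unusable.

    A record-level ``se`` (when stored in the corpus) takes precedence over
    the SE recomputed from the sample sizes.
    """
    if rec.metric == "r":
        effect = math.atanh(rec.value)
        if rec.se is not None:
            se = rec.se
        else:
            if rec.n1 < 4:
                return None
            se = se_of_r_fisher(rec.n1)
    else:
        effect = rec.value
        if rec.se is not None:
            se = rec.se
        else:
            if rec.n2 is None or rec.n1 < 2 or rec.n2 < 2:
                return None
            se = se_of_g(rec.value, rec.n1, rec.n2)
    p = p_value_z(effect, se)
    return FunnelPoint(
        meta_id=rec.meta_id,
        study_id=rec.study_id,
        metric=rec.metric,
        effect=effect,
        se=se,
        p=p,
        region=contour_region(p),
    )


def funnel_table(
    corpus: Corpus, subgroup: str = "all", metric: str | None = None
) -> FunnelSummary:
    """Region counts/percentages over every classifiable record."""
    records = corpus.select(metric=metric, subgroup=subgroup)
    if not records:
        raise ValueError(f"no records in subgroup={subgroup!r}")
    counts = {r: 0 for r in REGIONS}
    skipped = 0
    for rec in records:
        point = classify_record(rec)
        if point is None:
            skipped += 1
            continue
        counts[point.region] += 1
    n_classified = sum(counts.values())
    if n_classified == 0:
        raise ValueError("no classifiable records (all lacked usable sample sizes)")
    return FunnelSummary(
        subgroup=subgroup, counts=counts, n_classified=n_classified, n_skipped=skipped
    )


def funnel_plot_prep(
    corpus: Corpus, subgroup: str = "all", metric: str | None = None
) -> dict:
    """Points and contour boundaries for a one-directional funnel plot.

    Effects are plotted on the positive axis against SE, with SE increasing
    downward.  The contour boundaries are the loci ``effect = z_q * se`` for
    the .10/.05/.01 two-sided significance levels.
    """
    records = corpus.select(metric=metric, subgroup=subgroup)
    if not records:
        raise ValueError(f"no records in subgroup={subgroup!r}")
    points = [p for p in (classify_record(rec) for rec in records) if p is not None]
    if not points:
        raise ValueError("no classifiable records (all lacked usable sample sizes)")
    se = np.array([p.se for p in points])
    se_grid = np.linspace(0, se.max() * 1.05, 200)
    boundaries = {
        level: np.column_stack([z * se_grid, se_grid]) for level, z in CONTOUR_Z.items()
    }
    return {
        "points": points,
        "effect": np.array([p.effect for p in points]),
        "se": se,
        "region": np.array([p.region for p in points]),
        "boundaries": boundaries,
        "y_increases_downward": True,
    }
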