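"""Effect-size corpora: records, validation, CSV io, and normalization.

A corpus is a flat collection of effect sizes extracted from published
meta-analyses.  Each record carries a metric (Pearson's ``r`` for
individual-differences designs, Cohen's ``d`` or Hedges' ``g`` for
group-difference designs), the effect magnitude, and the sample sizes
behind it.  Correlational records store the total n in ``n1`` and leave
``n2`` unset.

Normalization follows standard meta-research practice when only the
distribution of magnitudes (not directions) is of interest: effects are
replaced by their absolute values, and Cohen's ``d`` values are converted
to Hedges' ``g`` via the small-sample bias correction so that all
group-difference effects live on one comparable scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd

__all__ = [
    "EffectRecord",
    "Corpus",
    "CorpusError",
    "SchemaError",
    "RowError",
    "load_corpus",
    "save_corpus",
    "normalize",
    "d_to_g",
    "CSV_COLUMNS",
]

METRICS = ("r", "d", "g")
CATEGORIES = ("biomedical", "psychosocial", "unclassified")
CSV_COLUMNS = ["meta_id", "study_id", "metric", "value", "n1", "n2", "category"]


class CorpusError(ValueError):
    """Base class for corpus validation failures."""


class SchemaError(CorpusError):
    """The CSV is missing required columns."""


class RowError(CorpusError):
    """One or more rows failed validation; message lists each by index."""

    def __init__(self, messages: list[str]):
        self.messages = list(messages)
        super().__init__("\n".join(self.messages))


@dataclass(frozen=True)
class EffectRecord:
    """A single extracted effect size.

    Parameters
    ----------
    meta_id, study_id
        Opaque identifiers for the source meta-analysis and study.
    metric
        ``"r"``, ``"d"``, or ``"g"``.
    value
        Effect magnitude (may be negative before normalization).
    n1
        Group-1 size, or the total n for correlational designs.
    n2
        Group-2 size; ``None`` for correlational designs.
    category
        ``"biomedical"``, ``"psychosocial"``, or ``"unclassified"``.
    se
        Optional pre-computed standard error (Fisher-z scale for ``r``);
        when present it takes precedence over the recomputed value in
        funnel classification.
    """

    meta_id: str
    study_id: str
    metric: str
    value: float
    n1: int
    n2: int | None = None
    category: str = "unclassified"
    se: float | None = None

    def validate(self) -> list[str]:
        """Return a list of invariant violations (empty when valid)."""
        problems: list[str] = []
        if self.metric not in METRICS:
            problems.append(f"metric must be one of {METRICS}, got {self.metric!r}")
            return problems
        if not math.isfinite(self.value):
            problems.append(f"value must be finite, got {self.value!r}")
        if self.category not in CATEGORIES:
            problems.append(
                f"category must be one of {CATEGORIES}, got {self.category!r}"
            )
        if self.metric == "r":
            if abs(self.value) >= 1:
                problems.append(f"|r| must be < 1, got {self.value}")
            if self.n2 is not None:
                problems.append("correlational records must leave n2 unset")
            if self.n1 < 4:
                problems.append(f"correlational records require n1 >= 4, got {self.n1}")
        else:
            if self.n1 < 2:
                problems.append(f"group records require n1 >= 2, got {self.n1}")
            if self.n2 is None or self.n2 < 2:
                problems.append(f"group records require n2 >= 2, got {self.n2}")
        if self.se is not None and self.se <= 0:
            problems.append(f"se must be positive when given, got {self.se}")
        return problems


@dataclass
class Corpus:
    """An ordered, validated collection of :class:`EffectRecord`."""

    records: list[EffectRecord] = field(default_factory=list)
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[EffectRecord]:
        return iter(self.records)

    def counts_by_metric(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for rec in self.records:
            counts[rec.metric] = counts.get(rec.metric, 0) + 1
        return counts

    def select(self, metric: str | None = None, subgroup: str = "all") -> list[EffectRecord]:
        """Records filtered by metric and category subgroup."""
        out = []
        for rec in self.records:
            if metric is not None and rec.metric != metric:
                continue
            if subgroup != "all" and rec.category != subgroup:
                continue
            out.append(rec)
        return out

    def values(self, metric: str | None = None, subgroup: str = "all") -> list[float]:
        return [rec.value for rec in self.select(metric, subgroup)]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for rec in self.records:
            rows.append(
                {
                    "meta_id": rec.meta_id,
                    "study_id": rec.study_id,
                    "metric": rec.metric,
                    "value": rec.value,
                    "n1": rec.n1,
                    "n2": rec.n2,
                    "category": rec.category,
                    "se": rec.se,
                }
            )
        frame = pd.DataFrame(rows, columns=CSV_COLUMNS + ["se"])
        if frame["se"].isna().all():
            frame = frame.drop(columns=["se"])
        return frame


def validate_records(records: Iterable[EffectRecord]) -> None:
    """Raise :class:`RowError` listing every invalid record by index."""
    messages = []
    for i, rec in enumerate(records):
        for problem in rec.validate():
            messages.append(f"record {i}: {problem}")
    if messages:
        raise RowError(messages)


def _parse_row(i: int, row: pd.Series, errors: list[str]) -> EffectRecord | None:
    try:
        value = float(row["value"])
    except (TypeError, ValueError):
        errors.append(f"row {i}: non-numeric value {row['value']!r}")
        return None
    metric = str(row["metric"]).strip()

    def parse_n(col: str) -> int | None:
        raw = row.get(col)
        if raw is None or (isinstance(raw, float) and math.isnan(raw)) or raw == "":
            return None
        try:
            n_float = float(raw)
        except (TypeError, ValueError):
            errors.append(f"row {i}: non-numeric {col} {raw!r}")
            return None
        if n_float != int(n_float):
            errors.append(f"row {i}: {col} must be an integer, got {raw!r}")
            return None
        return int(n_float)

    n1 = parse_n("n1")
    n2 = parse_n("n2")
    if n1 is None:
        errors.append(f"row {i}: missing n1")
        return None

    category = row.get("category")
    if category is None or (isinstance(category, float) and math.isnan(category)) or str(category).strip() == "":
        category = "unclassified"
    else:
        category = str(category).strip()

    se_raw = row.get("se")
    se = None
    if se_raw is not None and not (isinstance(se_raw, float) and math.isnan(se_raw)) and se_raw != "":
        try:
            se = float(se_raw)
        except (TypeError, ValueError):
            errors.append(f"row {i}: non-numeric se {se_raw!r}")
            return None

    rec = EffectRecord(
        meta_id=str(row["meta_id"]),
        study_id=str(row["study_id"]),
        metric=metric,
        value=value,
        n1=n1,
        n2=n2,
        category=category,
        se=se,
    )
    problems = rec.validate()
    if problems:
        errors.extend(f"row {i}: {p}" for p in problems)
        return None
    return rec


def load_corpus(path: str | Path, **read_csv_kwargs) -> Corpus:
    """Read a corpus from a comma-delimited UTF-8 CSV with header.

    Required columns: ``meta_id, study_id, metric, value, n1, n2, category``
    (``n2`` and ``category`` may be empty per row; ``se`` is optional).
    Rows failing validation are rejected collectively with row-indexed
    messages.
    """
    path = Path(path)
    frame = pd.read_csv(path, dtype={"meta_id": str, "study_id": str}, **read_csv_kwargs)
    required = {"meta_id", "study_id", "metric", "value", "n1"}
    missing = required - set(frame.columns)
    if missing:
        raise SchemaError(f"missing required column(s): {sorted(missing)}")
    if "n2" not in frame.columns:
        frame["n2"] = None
    if "category" not in frame.columns:
        frame["category"] = None

    errors: list[str] = []
    records: list[EffectRecord] = []
    for i, row in frame.iterrows():
        rec = _parse_row(int(i), row, errors)
        if rec is not None:
            records.append(rec)
    if errors:
        raise RowError(errors)
    return Corpus(records=records, provenance=str(path))


def save_corpus(corpus: Corpus, path: str | Path) -> None:
    """Write the corpus back out with the same schema the reader expects."""
    corpus.to_frame().to_csv(path, index=False)


def d_to_g(d: float, n1: int, n2: int) -> float:
    """Convert Cohen's d to Hedges' g with the small-sample bias correction.

    g = d * (1 - 3 / (4*(n1 + n2) - 9)).  The correction factor lies in
    (0, 1) and tends to 1 as the total sample size grows, so |g| <= |d|
    with the sign preserved.
    """
    n_total = n1 + n2
    if n_total <= 2:
        raise ValueError(f"total sample size must exceed 2, got {n_total}")
    return d * (1.0 - 3.0 / (4.0 * n_total - 9.0))


def normalize(corpus: Corpus) -> Corpus:
    """Absolute-value all effects and convert every d record to g.

    Idempotent: g and r records only lose their sign; d records are
    bias-corrected exactly once (their metric becomes ``g``).
    """
    out = []
    errors = []
    for i, rec in enumerate(corpus.records):
        value = abs(rec.value)
        metric = rec.metric
        if metric == "d":
            if rec.n2 is None:
                errors.append(f"record {i}: d record lacks n2; cannot convert to g")
                continue
            value = d_to_g(value, rec.n1, rec.n2)
            metric = "g"
        out.append(replace(rec, value=value, metric=metric))
    if errors:
        raise RowError(errors)
    return Corpus(records=out, provenance=corpus.provenance)
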