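"""Descriptive summaries of a case series.

Reproduces the descriptive layer of a spontaneous-report case-series study:
counts and percentages by category (demographics, reporting country,
reporter qualification, suspected drug, seriousness, outcome, drug
withdrawal), median/IQR summaries of quantitative variables (age, time to
onset, monthly dose), and the ranking of co-reported event terms.

Every percentage is printed together with its denominator and the rule that
defines it, because denominators in case-series tables differ by row group
(all cases vs. cases with the field documented) and multi-select fields such
as reporter qualification can legitimately sum to more than 100%.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np

from ._util import round_half_up
from .errors import ValidationError
from .icsr import Report, ReportStore
from .terminology import DEFAULT_ROLE_FILTER, normalize_label

__all__ = [
    "SummaryRow",
    "SummaryTable",
    "QuantSummary",
    "AGE_BANDS",
    "categorical_summary",
    "quantitative_summary",
    "outcome_summary",
    "coreported_terms",
]

#: Age bands used in the demographics table (closed intervals in years).
AGE_BANDS: tuple[tuple[int, int, str], ...] = (
    (0, 17, "<18"),
    (18, 44, "18-44"),
    (45, 64, "45-64"),
    (65, 74, "65-74"),
    (75, 120, ">=75"),
)

#: Fields categorical_summary understands, and whether they are multi-select.
_FIELDS = {
    "country": False,
    "sex": False,
    "reporter_qualification": True,
    "age_band": False,
    "drug": True,
    "seriousness": False,
    "outcome": False,
    "drug_withdrawn": False,
}


@dataclass(frozen=True)
class SummaryRow:
    label: str
    count: int
    percent: float  # of the table's denominator, rounded half-up to 1 decimal


@dataclass(frozen=True)
class SummaryTable:
    """Counts and percents with an explicit denominator and its rule."""

    rows: tuple[SummaryRow, ...]
    denominator: int
    denominator_rule: str

    def count(self, label: str) -> int:
        for row in self.rows:
            if row.label == label:
                return row.count
        return 0

    def percent(self, label: str) -> float:
        for row in self.rows:
            if row.label == label:
                return row.percent
        return 0.0

    def to_records(self) -> list[dict]:
        return [
            {"label": r.label, "count": r.count, "percent": r.percent} for r in self.rows
        ]


@dataclass(frozen=True)
class QuantSummary:
    """Median with quartiles and range of a quantitative variable."""

    median: float
    q1: float
    q3: float
    min: float
    max: float
    n_nonmissing: int

    def to_dict(self) -> dict:
        return {
            "median": self.median,
            "q1": self.q1,
            "q3": self.q3,
            "min": self.min,
            "max": self.max,
            "n": self.n_nonmissing,
        }


def _age_band(age: float) -> str | None:
    for lo, hi, label in AGE_BANDS:
        if lo <= age <= hi:
            return label
    return None


def _field_values(report: Report, fld: str) -> list[str]:
    """Category labels a report contributes to, [] when the field is missing."""
    if fld == "country":
        return [report.country] if report.country else []
    if fld == "sex":
        return [report.sex] if report.sex else []
    if fld == "reporter_qualification":
        return sorted(set(report.reporter_qualifications))
    if fld == "age_band":
        if report.age_years is None:
            return []
        band = _age_band(report.age_years)
        return [band] if band else []
    if fld == "drug":
        return sorted(
            {d.ingredient for d in report.drugs if d.role in DEFAULT_ROLE_FILTER}
        )
    if fld == "seriousness":
        if report.serious is None:
            return []
        return ["serious" if report.serious else "non-serious"]
    if fld == "outcome":
        out = report.outcome
        return [out] if out else []
    if fld == "drug_withdrawn":
        if report.drug_withdrawn is None:
            return []
        return ["withdrawn" if report.drug_withdrawn else "not_withdrawn"]
    raise ValidationError(f"unknown field {fld!r}")


def categorical_summary(
    store: ReportStore,
    case_ids: Iterable[str],
    fld: str,
    denominator_rule: Literal["all_cases", "known"] = "all_cases",
) -> SummaryTable:
    """Counts by category among the case reports.

    Each report counts once per category it belongs to; multi-select fields
    (reporter qualification, suspected drug) may therefore sum to more than
    the denominator.  ``denominator_rule`` chooses between all cases and
    cases with the field documented; percents are 100·count/denominator
    rounded half-up to one decimal.
    """
    if fld not in _FIELDS:
        raise ValidationError(f"unknown field {fld!r}; one of {sorted(_FIELDS)}")
    ids = sorted(set(case_ids))
    missing = [rid for rid in ids if rid not in store]
    if missing:
        raise ValidationError(f"case ids not in store: {missing[:5]}")
    counts: dict[str, int] = {}
    n_known = 0
    for rid in ids:
        values = _field_values(store.get(rid), fld)
        if values:
            n_known += 1
        for v in values:
            counts[v] = counts.get(v, 0) + 1
    if denominator_rule == "all_cases":
        denom = len(ids)
        rule = "all case reports"
    elif denominator_rule == "known":
        denom = n_known
        rule = f"case reports with {fld} documented"
    else:
        raise ValidationError(f"unknown denominator rule {denominator_rule!r}")
    rows = tuple(
        SummaryRow(
            label=label,
            count=c,
            percent=round_half_up(100.0 * c / denom, 1) if denom else 0.0,
        )
        for label, c in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    )
    return SummaryTable(rows=rows, denominator=denom, denominator_rule=rule)


def quantitative_summary(values: Sequence[float | None]) -> QuantSummary:
    """Median, quartiles and range of the non-missing values.

    Quartiles use linear interpolation between order statistics (the default
    convention of ``numpy.percentile``); min and max are exact.
    """
    vals = np.asarray([v for v in values if v is not None], dtype=float)
    if vals.size == 0:
        raise ValidationError("no non-missing values to summarize")
    q1, med, q3 = np.percentile(vals, [25, 50, 75], method="linear")
    return QuantSummary(
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        min=float(vals.min()),
        max=float(vals.max()),
        n_nonmissing=int(vals.size),
    )


def outcome_summary(store: ReportStore, case_ids: Iterable[str]) -> SummaryTable:
    """Outcome distribution among cases with a documented outcome.

    The denominator is the number of cases whose report-level outcome is one
    of recovered / recovering / not_recovered / fatal; ``unknown`` counts as
    undocumented.  An all-missing case set yields an empty table with
    denominator zero.
    """
    table = categorical_summary(store, case_ids, "outcome", denominator_rule="known")
    return SummaryTable(
        rows=table.rows,
        denominator=table.denominator,
        denominator_rule="case reports with a documented outcome",
    )


def coreported_terms(
    store: ReportStore,
    case_ids: Iterable[str],
    exclude: set[str],
) -> list[tuple[str, int, float]]:
    """Rank the event terms co-reported with the index event among cases.

    ``exclude`` must contain the index event PT(s); excluded terms never
    appear in the output.  Counting is report-level; the list is ordered by
    count descending with ties broken lexicographically; percents are of all
    cases.
    """
    ids = sorted(set(case_ids))
    excluded = {normalize_label(p) for p in exclude}
    counts: dict[str, int] = {}
    for rid in ids:
        pts = {
            rx.pt
            for rx in store.get(rid).reactions
            if normalize_label(rx.pt) not in excluded
        }
        for pt in pts:
            counts[pt] = counts.get(pt, 0) + 1
    n = len(ids)
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0].casefold()))
    return [
        (pt, c, round_half_up(100.0 * c / n, 1) if n else 0.0) for pt, c in ranked
    ]
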