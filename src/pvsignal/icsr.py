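"""Individual case safety reports: data model, loading, indexing and queries.

An ICSR (individual case safety report) is one spontaneous report of one or
more suspected adverse drug reactions in one patient.  The store ingests the
three relational tables such reports are exchanged in (reports, report-drugs,
report-reactions), validates them against the event and drug dictionaries,
and answers report-level queries: *which reports contain this event and
involve this drug class?*

All counting in this package is report-level: a report contributes at most
one to any count no matter how many of its drug or reaction entries match.
"""

from __future__ import annotations

import csv
import datetime as _dt
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, NamedTuple

import pandas as pd

from .errors import ParseError, ValidationError
from .terminology import (
    ROLES,
    DrugDictionary,
    DrugQuery,
    TermDictionary,
    TermQuery,
    expand_drug_query,
    expand_term_query,
    normalize_label,
)

__all__ = [
    "DrugEntry",
    "ReactionEntry",
    "Report",
    "ReportStore",
    "RejectLog",
    "TimeToOnset",
    "load_reports",
    "match_reports",
    "time_to_onset",
    "monthly_dose",
    "parse_partial_date",
]

logger = logging.getLogger(__name__)

SERIOUSNESS_CRITERIA = frozenset(
    {
        "death",
        "life_threatening",
        "hospitalization",
        "disabling",
        "congenital_anomaly",
        "other_medically_important",
    }
)
OUTCOMES = frozenset({"recovered", "recovering", "not_recovered", "fatal", "unknown"})
REPORTER_QUALIFICATIONS = frozenset(
    {"physician", "pharmacist", "other_health_professional", "consumer", "lawyer"}
)
SEXES = frozenset({"female", "male"})

#: mass units convertible to milligrams for monthly-dose normalization
_MG_PER_UNIT = {"mg": 1.0, "g": 1000.0, "ug": 0.001, "mcg": 0.001, "µg": 0.001}


class ParsedDate(NamedTuple):
    date: _dt.date
    imputed: bool  # True when a partial (year-month) date was resolved


def parse_partial_date(value: str | None) -> ParsedDate | None:
    """Parse an ISO calendar date, tolerating partial year-month dates.

    Spontaneous reports commonly carry partial dates; a ``YYYY-MM`` value is
    resolved to the 15th of the month and flagged as imputed.  Year-only
    dates are too coarse for day-resolution arithmetic and parse as missing.
    """
    if value is None:
        return None
    s = str(value).strip()
    if not s:
        return None
    try:
        return ParsedDate(_dt.date.fromisoformat(s), imputed=False)
    except ValueError:
        pass
    parts = s.split("-")
    if len(parts) == 2:
        try:
            return ParsedDate(_dt.date(int(parts[0]), int(parts[1]), 15), imputed=True)
        except ValueError:
            pass
    if len(parts) == 1 and s.isdigit() and len(s) == 4:
        return None  # year-only: too coarse for day-resolution arithmetic
    raise ValidationError(f"unparseable date {value!r}")


@dataclass(frozen=True, slots=True)
class DrugEntry:
    """One drug on a report, with role, dosing and administration dates."""

    ingredient: str
    role: str
    dose_amount: float | None = None
    dose_unit: str | None = None
    dose_interval_days: float | None = None
    start_date: _dt.date | None = None
    end_date: _dt.date | None = None
    indication: str | None = None
    start_imputed: bool = False

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValidationError(f"unknown drug role {self.role!r}")
        if self.dose_amount is not None and not self.dose_amount > 0:
            raise ValidationError("dose_amount must be positive when present")
        if (
            self.start_date is not None
            and self.end_date is not None
            and self.end_date < self.start_date
        ):
            raise ValidationError("end_date precedes start_date")


@dataclass(frozen=True, slots=True)
class ReactionEntry:
    """One reported reaction (a MedDRA-style PT) with seriousness and outcome."""

    pt: str
    onset_date: _dt.date | None = None
    serious: bool | None = None
    seriousness_criteria: frozenset[str] = frozenset()
    outcome: str | None = None
    onset_imputed: bool = False

    def __post_init__(self) -> None:
        if self.seriousness_criteria and self.serious is not True:
            raise ValidationError(
                "seriousness_criteria given but reaction not marked serious"
            )
        if not self.seriousness_criteria <= SERIOUSNESS_CRITERIA:
            raise ValidationError(
                f"unknown seriousness criteria "
                f"{set(self.seriousness_criteria) - SERIOUSNESS_CRITERIA}"
            )
        if self.outcome is not None and self.outcome not in OUTCOMES:
            raise ValidationError(f"unknown outcome {self.outcome!r}")


@dataclass(frozen=True, slots=True)
class Report:
    """One individual case safety report."""

    report_id: str
    drugs: tuple[DrugEntry, ...]
    reactions: tuple[ReactionEntry, ...]
    country: str | None = None
    reporter_qualifications: tuple[str, ...] = ()
    sex: str | None = None
    age_years: float | None = None
    drug_withdrawn: bool | None = None

    def __post_init__(self) -> None:
        if not str(self.report_id).strip():
            raise ValidationError("report_id must be non-empty")
        if len(self.drugs) < 1:
            raise ValidationError(f"report {self.report_id}: no drug entries")
        if len(self.reactions) < 1:
            raise ValidationError(f"report {self.report_id}: no reaction entries")
        if self.sex is not None and self.sex not in SEXES:
            raise ValidationError(f"report {self.report_id}: unknown sex {self.sex!r}")
        if self.age_years is not None and not 0 <= self.age_years <= 120:
            raise ValidationError(
                f"report {self.report_id}: age {self.age_years} outside [0, 120]"
            )
        for q in self.reporter_qualifications:
            if q not in REPORTER_QUALIFICATIONS:
                raise ValidationError(
                    f"report {self.report_id}: unknown reporter qualification {q!r}"
                )

    @property
    def serious(self) -> bool | None:
        """Report-level seriousness: True if any reaction is serious."""
        flags = [r.serious for r in self.reactions]
        if any(f is True for f in flags):
            return True
        if any(f is False for f in flags):
            return False
        return None

    @property
    def outcome(self) -> str | None:
        """Report-level outcome: the worst non-missing reaction outcome.

        Severity order fatal > not_recovered > recovering > recovered;
        ``unknown`` is treated as missing.
        """
        order = {"fatal": 0, "not_recovered": 1, "recovering": 2, "recovered": 3}
        known = [r.outcome for r in self.reactions if r.outcome in order]
        if not known:
            return None
        return min(known, key=order.__getitem__)


@dataclass
class RejectLog:
    """Rows and reports set aside during loading — collected, never dropped silently."""

    orphan_drug_rows: int = 0
    orphan_reaction_rows: int = 0
    invalid_reports: list[tuple[str, str]] = field(default_factory=list)
    unresolved_pts: list[tuple[str, str]] = field(default_factory=list)
    unresolved_ingredients: list[tuple[str, str]] = field(default_factory=list)

    def summary(self) -> str:
        return (
            f"rejects: {self.orphan_drug_rows} orphan drug rows, "
            f"{self.orphan_reaction_rows} orphan reaction rows, "
            f"{len(self.invalid_reports)} invalid reports, "
            f"{len(self.unresolved_pts)} unresolved PTs, "
            f"{len(self.unresolved_ingredients)} unresolved ingredients"
        )


class ReportStore:
    """An indexed collection of reports plus the dictionaries they resolve in.

    Reaction PTs that do not resolve in the term dictionary and ingredients
    unknown to the drug dictionary are flagged in :attr:`rejects` at
    construction; the reports themselves are kept.
    """

    def __init__(
        self,
        reports: Iterable[Report],
        term_dict: TermDictionary,
        drug_dict: DrugDictionary,
        rejects: RejectLog | None = None,
    ):
        self.term_dict = term_dict
        self.drug_dict = drug_dict
        self.rejects = rejects if rejects is not None else RejectLog()
        self._reports: dict[str, Report] = {}
        for rep in reports:
            if rep.report_id in self._reports:
                raise ValidationError(f"duplicate report_id {rep.report_id!r}")
            self._reports[rep.report_id] = rep
        self._flag_unresolved()
        self._pt_index: dict[str, set[str]] | None = None
        self._drug_index: dict[str, dict[str, set[str]]] | None = None

    def _flag_unresolved(self) -> None:
        for rep in self._reports.values():
            for rx in rep.reactions:
                if rx.pt not in self.term_dict:
                    self.rejects.unresolved_pts.append((rep.report_id, rx.pt))
            for d in rep.drugs:
                if d.ingredient not in self.drug_dict:
                    self.rejects.unresolved_ingredients.append(
                        (rep.report_id, d.ingredient)
                    )

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self._reports)

    def __iter__(self) -> Iterator[Report]:
        return iter(self._reports.values())

    def __contains__(self, report_id: str) -> bool:
        return report_id in self._reports

    def get(self, report_id: str) -> Report:
        return self._reports[report_id]

    @property
    def report_ids(self) -> set[str]:
        return set(self._reports)

    # -- inverted indexes ---------------------------------------------------
    def _build_indexes(self) -> None:
        pt_index: dict[str, set[str]] = {}
        drug_index: dict[str, dict[str, set[str]]] = {}
        for rep in self._reports.values():
            for rx in rep.reactions:
                pt_index.setdefault(normalize_label(rx.pt), set()).add(rep.report_id)
            for d in rep.drugs:
                drug_index.setdefault(normalize_label(d.ingredient), {}).setdefault(
                    d.role, set()
                ).add(rep.report_id)
        self._pt_index = pt_index
        self._drug_index = drug_index

    def ids_with_pt(self, pts: Iterable[str]) -> set[str]:
        if self._pt_index is None:
            self._build_indexes()
        assert self._pt_index is not None
        out: set[str] = set()
        for pt in pts:
            out |= self._pt_index.get(normalize_label(pt), set())
        return out

    def ids_with_ingredient(
        self, ingredients: Iterable[str], roles: frozenset[str]
    ) -> set[str]:
        if self._drug_index is None:
            self._build_indexes()
        assert self._drug_index is not None
        out: set[str] = set()
        for ing in ingredients:
            by_role = self._drug_index.get(normalize_label(ing), {})
            for role in roles:
                out |= by_role.get(role, set())
        return out

    # -- output -------------------------------------------------------------
    def to_csvs(self, outdir: str | Path) -> None:
        """Write the three relational tables (reports, drugs, reactions)."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)

        def fmt(v) -> str:
            if v is None:
                return ""
            if isinstance(v, bool):
                return "true" if v else "false"
            if isinstance(v, float) and v == int(v):
                return str(int(v))
            return str(v)

        with open(outdir / "reports.csv", "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            w.writerow(
                [
                    "report_id",
                    "country",
                    "reporter_qualification",
                    "sex",
                    "age_years",
                    "drug_withdrawn",
                ]
            )
            for r in self:
                w.writerow(
                    [
                        r.report_id,
                        fmt(r.country),
                        "|".join(r.reporter_qualifications),
                        fmt(r.sex),
                        fmt(r.age_years),
                        fmt(r.drug_withdrawn),
                    ]
                )
        with open(outdir / "report_drugs.csv", "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            w.writerow(
                [
                    "report_id",
                    "ingredient",
                    "role",
                    "dose_amount",
                    "dose_unit",
                    "dose_interval_days",
                    "start_date",
                    "end_date",
                    "indication",
                ]
            )
            for r in self:
                for d in r.drugs:
                    w.writerow(
                        [
                            r.report_id,
                            d.ingredient,
                            d.role,
                            fmt(d.dose_amount),
                            fmt(d.dose_unit),
                            fmt(d.dose_interval_days),
                            fmt(d.start_date),
                            fmt(d.end_date),
                            fmt(d.indication),
                        ]
                    )
        with open(
            outdir / "report_reactions.csv", "w", newline="", encoding="utf-8"
        ) as fh:
            w = csv.writer(fh)
            w.writerow(
                ["report_id", "pt", "onset_date", "serious", "seriousness_criteria", "outcome"]
            )
            for r in self:
                for rx in r.reactions:
                    w.writerow(
                        [
                            r.report_id,
                            rx.pt,
                            fmt(rx.onset_date),
                            fmt(rx.serious),
                            "|".join(sorted(rx.seriousness_criteria)),
                            fmt(rx.outcome),
                        ]
                    )


# ---------------------------------------------------------------------------
# loading


def _missing(v) -> bool:
    return v is None or (isinstance(v, str) and v.strip() == "")


def _opt_str(v) -> str | None:
    return None if _missing(v) else str(v).strip()


def _opt_float(v, what: str) -> float | None:
    if _missing(v):
        return None
    try:
        return float(v)
    except ValueError:
        raise ValidationError(f"unparseable number for {what}: {v!r}") from None


def _opt_bool(v, what: str) -> bool | None:
    if _missing(v):
        return None
    s = str(v).strip().lower()
    if s in ("true", "1", "yes", "y"):
        return True
    if s in ("false", "0", "no", "n"):
        return False
    raise ValidationError(f"unparseable boolean for {what}: {v!r}")


def _read_table(path: str | Path, required: set[str]) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False, na_values=[])
    missing_cols = required - set(df.columns)
    if missing_cols:
        raise ParseError(f"{path}: missing columns {sorted(missing_cols)}", line=1)
    return df


def load_reports(
    reports_path: str | Path,
    drugs_path: str | Path,
    reactions_path: str | Path,
    term_dict: TermDictionary,
    drug_dict: DrugDictionary,
) -> ReportStore:
    """Assemble a :class:`ReportStore` from the three relational CSV tables.

    The tables share the ``report_id`` key space.  Drug or reaction rows
    whose parent report is absent are rejected (counted in the reject log);
    reports with zero drugs or zero reactions, or with invalid field values,
    are rejected per report with the reason recorded.
    """
    rej = RejectLog()
    reports_df = _read_table(reports_path, {"report_id"})
    drugs_df = _read_table(drugs_path, {"report_id", "ingredient", "role"})
    reactions_df = _read_table(reactions_path, {"report_id", "pt"})

    known_ids = set(reports_df["report_id"])
    orphan_drugs = ~drugs_df["report_id"].isin(known_ids)
    orphan_reactions = ~reactions_df["report_id"].isin(known_ids)
    rej.orphan_drug_rows = int(orphan_drugs.sum())
    rej.orphan_reaction_rows = int(orphan_reactions.sum())
    drugs_by_id = dict(tuple(drugs_df[~orphan_drugs].groupby("report_id", sort=False)))
    reactions_by_id = dict(
        tuple(reactions_df[~orphan_reactions].groupby("report_id", sort=False))
    )

    reports: list[Report] = []
    seen: set[str] = set()
    for row in reports_df.itertuples(index=False):
        rid = str(row.report_id).strip()
        try:
            if not rid:
                raise ValidationError("empty report_id")
            if rid in seen:
                raise ValidationError("duplicate report_id")
            seen.add(rid)
            drug_rows = drugs_by_id.get(rid)
            reaction_rows = reactions_by_id.get(rid)
            if drug_rows is None or len(drug_rows) == 0:
                raise ValidationError("no drug entries")
            if reaction_rows is None or len(reaction_rows) == 0:
                raise ValidationError("no reaction entries")
            drugs = tuple(_drug_entry(d) for d in drug_rows.itertuples(index=False))
            reactions = tuple(
                _reaction_entry(x) for x in reaction_rows.itertuples(index=False)
            )
            quals = _opt_str(getattr(row, "reporter_qualification", None))
            reports.append(
                Report(
                    report_id=rid,
                    country=_opt_str(getattr(row, "country", None)),
                    reporter_qualifications=(
                        tuple(q.strip() for q in quals.split("|")) if quals else ()
                    ),
                    sex=_opt_str(getattr(row, "sex", None)),
                    age_years=_opt_float(getattr(row, "age_years", None), "age_years"),
                    drug_withdrawn=_opt_bool(
                        getattr(row, "drug_withdrawn", None), "drug_withdrawn"
                    ),
                    drugs=drugs,
                    reactions=reactions,
                )
            )
        except ValidationError as exc:
            rej.invalid_reports.append((rid, str(exc)))
    store = ReportStore(reports, term_dict, drug_dict, rejects=rej)
    logger.info("loaded %d reports; %s", len(store), rej.summary())
    return store


def _drug_entry(row) -> DrugEntry:
    start = parse_partial_date(_opt_str(getattr(row, "start_date", None)))
    end = parse_partial_date(_opt_str(getattr(row, "end_date", None)))
    return DrugEntry(
        ingredient=str(row.ingredient).strip(),
        role=str(row.role).strip(),
        dose_amount=_opt_float(getattr(row, "dose_amount", None), "dose_amount"),
        dose_unit=_opt_str(getattr(row, "dose_unit", None)),
        dose_interval_days=_opt_float(
            getattr(row, "dose_interval_days", None), "dose_interval_days"
        ),
        start_date=start.date if start else None,
        end_date=end.date if end else None,
        indication=_opt_str(getattr(row, "indication", None)),
        start_imputed=bool(start.imputed) if start else False,
    )


def _reaction_entry(row) -> ReactionEntry:
    onset = parse_partial_date(_opt_str(getattr(row, "onset_date", None)))
    crit = _opt_str(getattr(row, "seriousness_criteria", None))
    return ReactionEntry(
        pt=str(row.pt).strip(),
        onset_date=onset.date if onset else None,
        serious=_opt_bool(getattr(row, "serious", None), "serious"),
        seriousness_criteria=(
            frozenset(c.strip() for c in crit.split("|")) if crit else frozenset()
        ),
        outcome=_opt_str(getattr(row, "outcome", None)),
        onset_imputed=bool(onset.imputed) if onset else False,
    )


# ---------------------------------------------------------------------------
# queries


def match_reports(
    store: ReportStore,
    term_query: TermQuery | None = None,
    drug_query: DrugQuery | None = None,
) -> set[str]:
    """Report ids matching an event query, a drug query, or their conjunction.

    A report matches a term query iff at least one of its reactions' PTs is
    in the expanded PT set; it matches a drug query iff at least one of its
    drug entries has an ingredient in the expanded set *and* a role in the
    query's role filter.  With both queries given, the intersection is
    returned.  A report counts once however many entries match.
    """
    if term_query is None and drug_query is None:
        raise ValidationError("at least one of term_query, drug_query is required")
    result: set[str] | None = None
    if term_query is not None:
        pts = expand_term_query(term_query, store.term_dict)
        result = store.ids_with_pt(pts)
    if drug_query is not None:
        ingredients = expand_drug_query(drug_query, store.drug_dict)
        if not ingredients:
            logger.warning("drug query %s expanded to an empty set", drug_query.label)
        hits = store.ids_with_ingredient(ingredients, drug_query.role_filter)
        result = hits if result is None else result & hits
    assert result is not None
    return result


class TimeToOnset(NamedTuple):
    """Days from earliest matching drug start to earliest reaction onset."""

    days: int
    imputed: bool  # either anchor date was resolved from a partial date
    implausible: bool  # negative interval (onset before drug start)


def time_to_onset(
    report: Report,
    drug_query: DrugQuery,
    drug_dict: DrugDictionary,
    term_query: TermQuery | None = None,
    term_dict: TermDictionary | None = None,
) -> TimeToOnset | None:
    """Time to onset for one report, anchored at the earliest matching drug start.

    The onset date is the earliest dated reaction (restricted to the term
    query's PT set when one is given); the anchor is the earliest start date
    among drug entries matching the query.  Missing either date yields
    missing.  Negative intervals are returned but flagged implausible.
    """
    ingredients = {normalize_label(i) for i in expand_drug_query(drug_query, drug_dict)}
    starts = [
        (d.start_date, d.start_imputed)
        for d in report.drugs
        if normalize_label(d.ingredient) in ingredients
        and d.role in drug_query.role_filter
        and d.start_date is not None
    ]
    if term_query is not None:
        if term_dict is None:
            raise ValidationError("term_dict required when term_query is given")
        pts = {normalize_label(p) for p in expand_term_query(term_query, term_dict)}
        candidates = [r for r in report.reactions if normalize_label(r.pt) in pts]
    else:
        candidates = list(report.reactions)
    onsets = [(r.onset_date, r.onset_imputed) for r in candidates if r.onset_date is not None]
    if not starts or not onsets:
        return None
    start, start_imp = min(starts)
    onset, onset_imp = min(onsets)
    days = (onset - start).days
    tto = TimeToOnset(days=days, imputed=start_imp or onset_imp, implausible=days < 0)
    if tto.implausible:
        logger.warning(
            "report %s: implausible negative time to onset (%d days)",
            report.report_id,
            days,
        )
    return tto


def monthly_dose(entry: DrugEntry) -> float | None:
    """Normalize a drug entry's dose to milligrams per 30-day month.

    Requires amount, unit and dosing interval; unconvertible units yield
    missing with a logged note.
    """
    if (
        entry.dose_amount is None
        or entry.dose_unit is None
        or entry.dose_interval_days is None
        or entry.dose_interval_days <= 0
    ):
        return None
    factor = _MG_PER_UNIT.get(entry.dose_unit.strip().lower())
    if factor is None:
        logger.info(
            "dose unit %r for %s not convertible to mg; treating dose as missing",
            entry.dose_unit,
            entry.ingredient,
        )
        return None
    return entry.dose_amount * factor * 30.0 / entry.dose_interval_days
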