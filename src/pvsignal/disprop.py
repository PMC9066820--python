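"""Case/non-case disproportionality statistics.

The central statistic is the Information Component (IC) of Bayesian
confidence propagation, the measure the Uppsala Monitoring Centre applies to
spontaneous-report databases.  For a drug–event pair the reports reduce to a
2×2 contingency table with observed count O (reports with both the drug and
the event), margins n_drug and n_event, and total N.  The expected count
under independence is E = n_drug · n_event / N, and the shrunk point
estimate is

    IC = log2((O + 1/2) / (E + 1/2)),

where the 1/2 continuity/shrinkage terms regularize small counts toward
zero.  The 95% credible interval comes from the gamma posterior of the
Poisson rate: IC025 and IC975 are log2 of the 2.5% and 97.5% quantiles of a
Gamma(shape = O + 1/2, rate = E + 1/2) distribution.  A closed-form
approximation of those bounds is also provided as a cross-check.  The
conventional signal threshold is IC025 > 0.

The comparator-restricted ("comparative") IC applies the same machinery
inside a scope limited to reports involving either the drug class of
interest or a comparator class, which mitigates confounding by indication
when both classes treat the same condition.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from .errors import ValidationError
from .icsr import ReportStore, match_reports
from .terminology import (
    DrugQuery,
    TermQuery,
    expand_drug_query,
    normalize_label,
)
from ._util import round_half_up

__all__ = [
    "ContingencyTable",
    "ICResult",
    "ComparativeSpec",
    "build_table",
    "information_component",
    "comparative_ic",
    "screen_all_pairs",
]

CiMethod = Literal["gamma_quantile", "noren_approx"]


@dataclass(frozen=True)
class ContingencyTable:
    """Report counts of a 2×2 case/non-case table.

    ``O`` observed reports with drug and event; ``n_drug`` and ``n_event``
    the margins; ``N`` the total number of reports in scope.
    """

    O: int
    n_drug: int
    n_event: int
    N: int

    def __post_init__(self) -> None:
        for name in ("O", "n_drug", "n_event", "N"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or isinstance(v, bool) or v < 0:
                raise ValidationError(f"{name} must be a non-negative integer, got {v!r}")
        if self.O > min(self.n_drug, self.n_event):
            raise ValidationError(
                f"O={self.O} exceeds a margin (n_drug={self.n_drug}, n_event={self.n_event})"
            )
        if self.n_drug > self.N or self.n_event > self.N:
            raise ValidationError("margins exceed total N")

    @property
    def expected(self) -> float:
        """E = n_drug · n_event / N, the count expected under independence."""
        if self.N == 0:
            raise ValidationError("N must be positive")
        return self.n_drug * self.n_event / self.N

    def cells(self) -> tuple[int, int, int, int]:
        """The four disjoint cells (both, drug-only, event-only, neither)."""
        return (
            self.O,
            self.n_drug - self.O,
            self.n_event - self.O,
            self.N - self.n_drug - self.n_event + self.O,
        )

    def scaled(self, k: int) -> "ContingencyTable":
        a, b, c, d = (k * x for x in self.cells())
        return ContingencyTable(O=a, n_drug=a + b, n_event=a + c, N=a + b + c + d)


@dataclass(frozen=True)
class ICResult:
    """An information-component estimate with its credible interval."""

    table: ContingencyTable
    E: float
    ic: float
    ic025: float
    ic975: float
    ci_method: CiMethod
    is_signal: bool
    drug_label: str | None = None
    event_label: str | None = None

    def rounded(self, ndigits: int = 1) -> tuple[float, float, float]:
        """(ic, ic025, ic975) rounded half-up, the display convention."""
        return (
            round_half_up(self.ic, ndigits),
            round_half_up(self.ic025, ndigits),
            round_half_up(self.ic975, ndigits),
        )

    def to_dict(self) -> dict:
        return {
            "drug": self.drug_label,
            "event": self.event_label,
            "O": self.table.O,
            "n_drug": self.table.n_drug,
            "n_event": self.table.n_event,
            "N": self.table.N,
            "E": self.E,
            "ic": self.ic,
            "ic025": self.ic025,
            "ic975": self.ic975,
            "ci_method": self.ci_method,
            "is_signal": self.is_signal,
        }


@dataclass(frozen=True)
class ComparativeSpec:
    """Event plus disjoint drug-of-interest / comparator queries."""

    event_query: TermQuery
    drug_of_interest: DrugQuery
    comparator: DrugQuery


def information_component(
    table: ContingencyTable, ci_method: CiMethod = "gamma_quantile"
) -> ICResult:
    """Shrunk IC point estimate and 95% credible interval for a 2×2 table.

    ``gamma_quantile`` takes exact quantiles of the Gamma(O + 1/2, E + 1/2)
    posterior; ``noren_approx`` uses the closed-form approximation

        IC025 ≈ IC − 3.3·(O+1/2)^(−1/2) − 2.0·(O+1/2)^(−3/2)
        IC975 ≈ IC + 2.4·(O+1/2)^(−1/2) − 0.5·(O+1/2)^(−3/2).
    """
    if table.N == 0:
        raise ValidationError("N must be positive")
    O = table.O
    E = table.expected
    ic = float(np.log2((O + 0.5) / (E + 0.5)))
    if ci_method == "gamma_quantile":
        lo, hi = stats.gamma.ppf([0.025, 0.975], a=O + 0.5, scale=1.0 / (E + 0.5))
        ic025, ic975 = float(np.log2(lo)), float(np.log2(hi))
    elif ci_method == "noren_approx":
        s = O + 0.5
        ic025 = ic - 3.3 * s ** (-0.5) - 2.0 * s ** (-1.5)
        ic975 = ic + 2.4 * s ** (-0.5) - 0.5 * s ** (-1.5)
    else:
        raise ValidationError(f"unknown ci_method {ci_method!r}")
    return ICResult(
        table=table,
        E=E,
        ic=ic,
        ic025=ic025,
        ic975=ic975,
        ci_method=ci_method,
        is_signal=ic025 > 0,
    )


def build_table(
    store: ReportStore,
    event_query: TermQuery,
    drug_query: DrugQuery,
    scope: set[str] | None = None,
) -> ContingencyTable:
    """Count reports into a 2×2 table, optionally within a scope of report ids.

    Counting is report-level: a report contributes at most one to each cell.
    """
    ids = store.report_ids if scope is None else set(scope) & store.report_ids
    if not ids:
        raise ValidationError("empty scope")
    with_event = match_reports(store, term_query=event_query) & ids
    with_drug = match_reports(store, drug_query=drug_query) & ids
    return ContingencyTable(
        O=len(with_event & with_drug),
        n_drug=len(with_drug),
        n_event=len(with_event),
        N=len(ids),
    )


def comparative_ic(
    store: ReportStore,
    spec: ComparativeSpec,
    ci_method: CiMethod = "gamma_quantile",
    overlap: Literal["keep", "exclude"] = "keep",
) -> ICResult:
    """IC of the event with the drug of interest, restricted to a comparator scope.

    The scope is the union of reports matching the drug of interest and
    reports matching the comparator.  Reports matching both classes go to
    the drug-of-interest row under ``overlap="keep"`` (exposure precedence)
    or are dropped from the scope under ``overlap="exclude"``.  The two drug
    queries must expand to disjoint ingredient sets.
    """
    interest_ings = {
        normalize_label(i)
        for i in expand_drug_query(spec.drug_of_interest, store.drug_dict)
    }
    comparator_ings = {
        normalize_label(i) for i in expand_drug_query(spec.comparator, store.drug_dict)
    }
    common = interest_ings & comparator_ings
    if common:
        raise ValidationError(
            f"drug-of-interest and comparator expansions overlap: {sorted(common)}"
        )
    with_interest = match_reports(store, drug_query=spec.drug_of_interest)
    with_comparator = match_reports(store, drug_query=spec.comparator)
    if overlap == "keep":
        scope = with_interest | with_comparator
    elif overlap == "exclude":
        scope = (with_interest | with_comparator) - (with_interest & with_comparator)
    else:
        raise ValidationError(f"unknown overlap policy {overlap!r}")
    table = build_table(store, spec.event_query, spec.drug_of_interest, scope=scope)
    result = information_component(table, ci_method)
    return replace(
        result,
        drug_label=spec.drug_of_interest.label,
        event_label=spec.event_query.label,
    )


def screen_all_pairs(
    store: ReportStore,
    drug_queries: Sequence[DrugQuery],
    event_queries: Sequence[TermQuery],
    ci_method: CiMethod = "gamma_quantile",
) -> list[ICResult]:
    """IC for every drug-query × event-query pair, full-database scope.

    Pairs with O = 0 are retained.  Results are ordered by IC025 descending
    (the screening statistic), ties broken by O descending, then by the
    drug/event labels lexicographically.
    """
    if not drug_queries or not event_queries:
        raise ValidationError("drug_queries and event_queries must be non-empty")
    results: list[ICResult] = []
    for dq in drug_queries:
        for eq in event_queries:
            table = build_table(store, eq, dq)
            res = information_component(table, ci_method)
            results.append(replace(res, drug_label=dq.label, event_label=eq.label))
    results.sort(
        key=lambda r: (-r.ic025, -r.table.O, r.drug_label or "", r.event_label or "")
    )
    return results
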