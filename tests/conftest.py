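"""Shared fixtures and independent counting oracles."""

from __future__ import annotations

import csv
import datetime as dt
from pathlib import Path

import pytest
from hypothesis import settings

from pvsignal.icsr import DrugEntry, ReactionEntry, Report, ReportStore
from pvsignal.synthetic import (
    comparative_fixture,
    default_drug_dictionary,
    default_term_dictionary,
    study_fixture,
)
from pvsignal.terminology import normalize_label

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def term_dict():
    return default_term_dictionary()


@pytest.fixture(scope="session")
def drug_dict():
    return default_drug_dictionary()


@pytest.fixture(scope="session")
def study_store():
    return study_fixture()


@pytest.fixture(scope="session")
def comp_store():
    return comparative_fixture()


@pytest.fixture(scope="session")
def raynaud_cases(study_store):
    from pvsignal.icsr import match_reports
    from pvsignal.terminology import DrugQuery, TermQuery

    return sorted(
        match_reports(
            study_store,
            term_query=TermQuery(level="PT", label="Raynaud's phenomenon"),
            drug_query=DrugQuery(mode="ATC_PREFIX", value="N02CD"),
        )
    )


@pytest.fixture()
def hand_store(term_dict, drug_dict):
    """Ten reports: 3 with erenumab, 4 with the index event, 2 with both."""

    def rep(i, ingredient, pt, role="suspected"):
        return Report(
            report_id=f"R{i:02d}",
            drugs=(DrugEntry(ingredient=ingredient, role=role),),
            reactions=(ReactionEntry(pt=pt),),
        )

    reports = [
        rep(1, "erenumab", "Raynaud's phenomenon"),
        rep(2, "erenumab", "Raynaud's phenomenon"),
        rep(3, "erenumab", "Headache"),
        rep(4, "sumatriptan", "Raynaud's phenomenon"),
        rep(5, "propranolol", "Raynaud's phenomenon"),
        rep(6, "sumatriptan", "Headache"),
        rep(7, "propranolol", "Nausea"),
        rep(8, "paracetamol", "Headache"),
        rep(9, "ibuprofen", "Dizziness"),
        rep(10, "topiramate", "Fatigue"),
    ]
    return ReportStore(reports, term_dict, drug_dict)


# ---------------------------------------------------------------------------
# independent oracle: a raw-row scan over the relational CSV tables


def brute_force_match(
    tmpdir: Path,
    pts: set[str] | None,
    ingredients: set[str] | None,
    roles: set[str],
) -> set[str]:
    """Re-derive a match set directly from the CSV rows, without the store.

    Reads the three tables written by ``ReportStore.to_csvs`` with the csv
    module only; report-level semantics fall out of collecting ids into sets.
    """
    want_pts = {normalize_label(p) for p in pts} if pts is not None else None
    want_ings = (
        {normalize_label(i) for i in ingredients} if ingredients is not None else None
    )
    all_ids: set[str] = set()
    with open(tmpdir / "reports.csv", newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            all_ids.add(row["report_id"])
    hit_event: set[str] = set()
    with open(tmpdir / "report_reactions.csv", newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            if want_pts is not None and normalize_label(row["pt"]) in want_pts:
                hit_event.add(row["report_id"])
    hit_drug: set[str] = set()
    with open(tmpdir / "report_drugs.csv", newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            if (
                want_ings is not None
                and normalize_label(row["ingredient"]) in want_ings
                and row["role"] in roles
            ):
                hit_drug.add(row["report_id"])
    result = all_ids
    if want_pts is not None:
        result = result & hit_event
    if want_ings is not None:
        result = result & hit_drug
    return result
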