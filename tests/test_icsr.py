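"""Report store loading, matching semantics, time-to-onset and dose."""

import dataclasses
import datetime as dt

import pytest

from conftest import brute_force_match
from pvsignal.errors import ParseError, ValidationError
from pvsignal.icsr import (
    DrugEntry,
    ReactionEntry,
    Report,
    ReportStore,
    load_reports,
    match_reports,
    monthly_dose,
    parse_partial_date,
    time_to_onset,
)
from pvsignal.synthetic import default_config, generate_store
from pvsignal.terminology import DrugQuery, TermQuery

RAYNAUD = "Raynaud's phenomenon"


def _write_tables(tmp_path, reports_rows, drug_rows, reaction_rows):
    (tmp_path / "reports.csv").write_text(
        "report_id,country,reporter_qualification,sex,age_years,drug_withdrawn\n"
        + "".join(r + "\n" for r in reports_rows),
        encoding="utf-8",
    )
    (tmp_path / "report_drugs.csv").write_text(
        "report_id,ingredient,role,dose_amount,dose_unit,dose_interval_days,"
        "start_date,end_date,indication\n" + "".join(r + "\n" for r in drug_rows),
        encoding="utf-8",
    )
    (tmp_path / "report_reactions.csv").write_text(
        "report_id,pt,onset_date,serious,seriousness_criteria,outcome\n"
        + "".join(r + "\n" for r in reaction_rows),
        encoding="utf-8",
    )
    return (
        tmp_path / "reports.csv",
        tmp_path / "report_drugs.csv",
        tmp_path / "report_reactions.csv",
    )


def test_load_fully_linked_tables(tmp_path, term_dict, drug_dict):
    reports = [f"R{i},,physician,female,40," for i in range(1, 6)]
    drugs = [f"R{i},erenumab,suspected,,,,,," for i in range(1, 6)] + [
        "R1,propranolol,concomitant,,,,,,",
        "R2,sumatriptan,suspected,,,,,,",
        "R3,paracetamol,interacting,,,,,,",
    ]
    reactions = [f"R{i},Headache,,,," for i in range(1, 6)] + ["R1,Nausea,,,,"]
    store = load_reports(*_write_tables(tmp_path, reports, drugs, reactions), term_dict, drug_dict)
    assert len(store) == 5
    assert store.rejects.orphan_drug_rows == 0
    assert len(store.get("R1").drugs) == 2


def test_orphan_rows_rejected_store_unchanged(tmp_path, term_dict, drug_dict):
    reports = ["R1,,,,,"]
    drugs = ["R1,erenumab,suspected,,,,,,", "R9,erenumab,suspected,,,,,,"]
    reactions = ["R1,Headache,,,,", "R9,Nausea,,,,"]
    store = load_reports(*_write_tables(tmp_path, reports, drugs, reactions), term_dict, drug_dict)
    assert len(store) == 1
    assert store.rejects.orphan_drug_rows == 1
    assert store.rejects.orphan_reaction_rows == 1


def test_unknown_pt_flagged_not_dropped(tmp_path, term_dict, drug_dict):
    reports = ["R1,,,,,"]
    drugs = ["R1,erenumab,suspected,,,,,,"]
    reactions = ["R1,Imaginitis,,,,"]
    store = load_reports(*_write_tables(tmp_path, reports, drugs, reactions), term_dict, drug_dict)
    assert len(store) == 1
    assert ("R1", "Imaginitis") in store.rejects.unresolved_pts


def test_report_without_reactions_rejected_per_report(tmp_path, term_dict, drug_dict):
    reports = ["R1,,,,,", "R2,,,,,"]
    drugs = ["R1,erenumab,suspected,,,,,,", "R2,erenumab,suspected,,,,,,"]
    reactions = ["R1,Headache,,,,"]
    store = load_reports(*_write_tables(tmp_path, reports, drugs, reactions), term_dict, drug_dict)
    assert len(store) == 1
    assert ("R2", "no reaction entries") in store.rejects.invalid_reports


def test_missing_key_column_is_parse_error(tmp_path, term_dict, drug_dict):
    (tmp_path / "reports.csv").write_text("id,country\nR1,\n", encoding="utf-8")
    (tmp_path / "report_drugs.csv").write_text("report_id,ingredient,role\n", encoding="utf-8")
    (tmp_path / "report_reactions.csv").write_text("report_id,pt\n", encoding="utf-8")
    with pytest.raises(ParseError, match="report_id"):
        load_reports(
            tmp_path / "reports.csv",
            tmp_path / "report_drugs.csv",
            tmp_path / "report_reactions.csv",
            term_dict,
            drug_dict,
        )


def test_match_semantics_and_once_per_report(term_dict, drug_dict):
    dup = Report(
        report_id="R1",
        drugs=(
            DrugEntry(ingredient="erenumab", role="suspected", dose_amount=70.0),
            DrugEntry(ingredient="erenumab", role="suspected", dose_amount=140.0),
        ),
        reactions=(ReactionEntry(pt=RAYNAUD),),
    )
    other = Report(
        report_id="R2",
        drugs=(DrugEntry(ingredient="sumatriptan", role="suspected"),),
        reactions=(ReactionEntry(pt=RAYNAUD),),
    )
    third = Report(
        report_id="R3",
        drugs=(DrugEntry(ingredient="galcanezumab", role="suspected"),),
        reactions=(ReactionEntry(pt="Headache"),),
    )
    store = ReportStore([dup, other, third], term_dict, drug_dict)
    both = match_reports(
        store,
        term_query=TermQuery(level="PT", label=RAYNAUD),
        drug_query=DrugQuery(mode="ATC_PREFIX", value="N02CD"),
    )
    assert both == {"R1"}  # duplicate ingredient entries count once
    drug_only = match_reports(store, drug_query=DrugQuery(mode="ATC_PREFIX", value="N02CD"))
    assert drug_only == {"R1", "R3"}
    with pytest.raises(ValidationError):
        match_reports(store)


def test_conjunction_equals_intersection_on_synthetic_store():
    store, _ = generate_store(default_config(n_reports=200, seed=3))
    tq = TermQuery(level="PT", label=RAYNAUD)
    dq = DrugQuery(mode="ATC_PREFIX", value="N02CD")
    assert match_reports(store, tq, dq) == (
        match_reports(store, term_query=tq) & match_reports(store, drug_query=dq)
    )


def test_widening_role_filter_is_monotone(term_dict, drug_dict):
    reports = [
        Report(
            report_id=f"R{i}",
            drugs=(DrugEntry(ingredient="propranolol", role=role),),
            reactions=(ReactionEntry(pt="Headache"),),
        )
        for i, role in enumerate(["suspected", "interacting", "concomitant"], 1)
    ]
    store = ReportStore(reports, term_dict, drug_dict)
    sets = []
    for roles in (
        {"suspected"},
        {"suspected", "interacting"},
        {"suspected", "interacting", "concomitant"},
    ):
        q = DrugQuery(
            mode="INGREDIENT_SET", value=frozenset({"propranolol"}), role_filter=frozenset(roles)
        )
        sets.append(match_reports(store, drug_query=q))
    assert sets[0] <= sets[1] <= sets[2]
    assert sets[2] == {"R1", "R2", "R3"}


def test_counting_oracle_reproduces_match_reports(tmp_path):
    """A raw CSV scan and the indexed store agree exactly on a 100-report store."""
    store, _ = generate_store(default_config(n_reports=100, seed=11))
    store.to_csvs(tmp_path)
    tq = TermQuery(level="PT", label="Headache")
    dq = DrugQuery(mode="ATC_PREFIX", value="N02C")
    from pvsignal.terminology import expand_drug_query, expand_term_query

    pts = expand_term_query(tq, store.term_dict)
    ings = expand_drug_query(dq, store.drug_dict)
    roles = set(dq.role_filter)
    assert match_reports(store, term_query=tq) == brute_force_match(tmp_path, pts, None, roles)
    assert match_reports(store, drug_query=dq) == brute_force_match(tmp_path, None, ings, roles)
    assert match_reports(store, tq, dq) == brute_force_match(tmp_path, pts, ings, roles)


# ---------------------------------------------------------------------------
# time to onset and dose


def _tto_report(start, onset, ingredient="erenumab"):
    sd = parse_partial_date(start)
    od = parse_partial_date(onset)
    return Report(
        report_id="T1",
        drugs=(
            DrugEntry(
                ingredient=ingredient,
                role="suspected",
                start_date=sd.date if sd else None,
                start_imputed=sd.imputed if sd else False,
            ),
        ),
        reactions=(
            ReactionEntry(
                pt=RAYNAUD,
                onset_date=od.date if od else None,
                onset_imputed=od.imputed if od else False,
            ),
        ),
    )


@pytest.mark.parametrize(
    "start,onset,days",
    [("2021-01-01", "2021-03-26", 84), ("2021-01-01", "2021-01-01", 0)],
)
def test_time_to_onset_days(drug_dict, start, onset, days):
    q = DrugQuery(mode="ATC_PREFIX", value="N02CD")
    tto = time_to_onset(_tto_report(start, onset), q, drug_dict)
    assert tto is not None and tto.days == days and not tto.implausible


def test_time_to_onset_missing_and_negative(drug_dict):
    q = DrugQuery(mode="ATC_PREFIX", value="N02CD")
    assert time_to_onset(_tto_report(None, "2021-03-26"), q, drug_dict) is None
    neg = time_to_onset(_tto_report("2021-03-26", "2021-01-01"), q, drug_dict)
    assert neg is not None and neg.days == -84 and neg.implausible


def test_partial_dates_resolve_to_mid_month_and_flag_imputed(drug_dict):
    q = DrugQuery(mode="ATC_PREFIX", value="N02CD")
    tto = time_to_onset(_tto_report("2021-01", "2021-02"), q, drug_dict)
    assert tto is not None and tto.days == 31 and tto.imputed  # Jan 15 -> Feb 15
    assert parse_partial_date("2021") is None  # year-only is too coarse
    with pytest.raises(ValidationError):
        parse_partial_date("not-a-date")


def test_tto_anchor_is_earliest_matching_drug_start(drug_dict):
    rep = Report(
        report_id="T2",
        drugs=(
            DrugEntry(ingredient="erenumab", role="suspected", start_date=dt.date(2021, 3, 1)),
            DrugEntry(ingredient="galcanezumab", role="suspected", start_date=dt.date(2021, 1, 1)),
            DrugEntry(ingredient="propranolol", role="suspected", start_date=dt.date(2020, 1, 1)),
        ),
        reactions=(ReactionEntry(pt=RAYNAUD, onset_date=dt.date(2021, 3, 26)),),
    )
    q = DrugQuery(mode="ATC_PREFIX", value="N02CD")
    tto = time_to_onset(rep, q, drug_dict)
    assert tto is not None and tto.days == 84  # anchored on galcanezumab, not propranolol


@pytest.mark.parametrize(
    "amount,unit,interval,expected",
    [
        (70.0, "mg", 30.0, 70.0),
        (225.0, "mg", 30.0, 225.0),
        (1.0, "mg", 15.0, 2.0),
        (0.07, "g", 30.0, 70.0),
        (70.0, "IU", 30.0, None),  # unconvertible unit
        (70.0, "mg", None, None),
    ],
)
def test_monthly_dose_normalization(amount, unit, interval, expected):
    entry = DrugEntry(
        ingredient="erenumab",
        role="suspected",
        dose_amount=amount,
        dose_unit=unit,
        dose_interval_days=interval,
    )
    result = monthly_dose(entry)
    if expected is None:
        assert result is None
    else:
        assert result == pytest.approx(expected)


def test_report_invariants():
    with pytest.raises(ValidationError):
        Report(report_id="X", drugs=(), reactions=(ReactionEntry(pt="Headache"),))
    with pytest.raises(ValidationError):
        Report(
            report_id="X",
            drugs=(DrugEntry(ingredient="erenumab", role="suspected"),),
            reactions=(),
        )
    with pytest.raises(ValidationError):
        DrugEntry(ingredient="x", role="suspected", dose_amount=-1.0)
    with pytest.raises(ValidationError):
        ReactionEntry(pt="Headache", serious=False, seriousness_criteria=frozenset({"disabling"}))
    with pytest.raises(ValidationError):
        Report(
            report_id="X",
            drugs=(DrugEntry(ingredient="erenumab", role="suspected"),),
            reactions=(ReactionEntry(pt="Headache"),),
            age_years=130.0,
        )
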