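"""Contingency tables, the information component and its credible intervals."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import integrate

from pvsignal.disprop import (
    ComparativeSpec,
    ContingencyTable,
    build_table,
    comparative_ic,
    information_component,
    screen_all_pairs,
)
from pvsignal.errors import ValidationError
from pvsignal.icsr import match_reports
from pvsignal.synthetic import default_config, generate_store
from pvsignal.terminology import DrugQuery, TermQuery

RAYNAUD = "Raynaud's phenomenon"


# ---------------------------------------------------------------------------
# contingency tables


def test_build_table_hand_counts(hand_store):
    table = build_table(
        hand_store,
        TermQuery(level="PT", label=RAYNAUD),
        DrugQuery(mode="INGREDIENT_SET", value=frozenset({"erenumab"})),
    )
    assert (table.O, table.n_drug, table.n_event, table.N) == (2, 3, 4, 10)


def test_build_table_scope_restriction(hand_store):
    dq = DrugQuery(mode="INGREDIENT_SET", value=frozenset({"erenumab"}))
    scope = match_reports(hand_store, drug_query=dq)
    table = build_table(hand_store, TermQuery(level="PT", label=RAYNAUD), dq, scope=scope)
    assert table.N == 3 and table.n_drug == 3 and table.O == 2
    with pytest.raises(ValidationError, match="empty scope"):
        build_table(hand_store, TermQuery(level="PT", label=RAYNAUD), dq, scope=set())


def test_build_table_agrees_with_raw_row_scan(tmp_path):
    """Independent CSV-scan oracle reproduces the table on 200 random reports."""
    from conftest import brute_force_match
    from pvsignal.terminology import expand_drug_query, expand_term_query

    store, _ = generate_store(default_config(n_reports=200, seed=17))
    store.to_csvs(tmp_path)
    tq = TermQuery(level="PT", label="Nausea")
    dq = DrugQuery(mode="ATC_PREFIX", value="N02")
    pts = expand_term_query(tq, store.term_dict)
    ings = expand_drug_query(dq, store.drug_dict)
    roles = set(dq.role_filter)
    ev = brute_force_match(tmp_path, pts, None, roles)
    dr = brute_force_match(tmp_path, None, ings, roles)
    table = build_table(store, tq, dq)
    assert (table.O, table.n_drug, table.n_event, table.N) == (
        len(ev & dr), len(dr), len(ev), 200,
    )


def test_table_invariants_enforced():
    with pytest.raises(ValidationError):
        ContingencyTable(O=5, n_drug=3, n_event=10, N=100)
    with pytest.raises(ValidationError):
        ContingencyTable(O=1, n_drug=3, n_event=101, N=100)
    with pytest.raises(ValidationError):
        ContingencyTable(O=-1, n_drug=3, n_event=4, N=100)


# ---------------------------------------------------------------------------
# the information component


def test_ic_point_estimate_matches_shrunk_log_ratio():
    # comparator-restricted cells: 99 + 55,506 class reports vs 43 + 47,417
    table = ContingencyTable(O=99, n_drug=55_605, n_event=142, N=103_065)
    res = information_component(table)
    assert res.E == pytest.approx(55_605 * 142 / 103_065)
    assert res.ic == pytest.approx(math.log2(99.5 / (res.E + 0.5)))
    assert res.ic == pytest.approx(0.37, abs=0.005)
    assert res.rounded()[0] == 0.4


def test_ic_zero_when_observed_equals_expected():
    res = information_component(ContingencyTable(O=10, n_drug=100, n_event=100, N=1000))
    assert res.E == pytest.approx(10.0)
    assert res.ic == 0.0


def test_ic_zero_with_empty_margin_and_wide_interval():
    res = information_component(ContingencyTable(O=0, n_drug=0, n_event=10, N=100))
    assert res.E == 0.0 and res.ic == 0.0
    assert res.ic975 - res.ic025 > 3.0  # almost no information at O = 0
    assert not res.is_signal


def test_gamma_interval_matches_quadrature_of_posterior():
    """2.5%/97.5% quantiles checked against numeric integration of the
    Gamma(O+1/2, E+1/2) density (the comparator-restricted case, O=99)."""
    O = 99
    E = 55_605 * 142 / 103_065  # ~76.61
    shape, rate = O + 0.5, E + 0.5

    def density(x: float) -> float:
        return rate**shape * x ** (shape - 1) * math.exp(-rate * x) / math.gamma(shape)

    res = information_component(ContingencyTable(O=99, n_drug=55_605, n_event=142, N=103_065))
    lo, hi = 2.0**res.ic025, 2.0**res.ic975
    mass_lo, _ = integrate.quad(density, 0, lo)
    mass_hi, _ = integrate.quad(density, 0, hi)
    assert mass_lo == pytest.approx(0.025, abs=1e-6)
    assert mass_hi == pytest.approx(0.975, abs=1e-6)


def test_approximate_interval_formula():
    table = ContingencyTable(O=99, n_drug=55_605, n_event=142, N=103_065)
    res = information_component(table, ci_method="noren_approx")
    s = 99.5
    assert res.ic025 == pytest.approx(res.ic - 3.3 * s**-0.5 - 2.0 * s**-1.5)
    assert res.ic975 == pytest.approx(res.ic + 2.4 * s**-0.5 - 0.5 * s**-1.5)
    assert res.ic025 <= res.ic <= res.ic975


@given(o=st.integers(min_value=0, max_value=99))
def test_ic_strictly_increasing_in_observed(o):
    margins = dict(n_drug=100, n_event=100, N=10_000)
    a = information_component(ContingencyTable(O=o, **margins))
    b = information_component(ContingencyTable(O=o + 1, **margins))
    assert b.ic > a.ic


@given(nd=st.integers(min_value=50, max_value=999))
def test_ic_strictly_decreasing_in_drug_margin(nd):
    a = information_component(ContingencyTable(O=20, n_drug=nd, n_event=1000, N=100_000))
    b = information_component(ContingencyTable(O=20, n_drug=nd + 1, n_event=1000, N=100_000))
    assert b.ic < a.ic


@pytest.mark.parametrize("ratio", [0.5, 1.0, 2.0])
def test_interval_width_decreases_with_observed(ratio):
    widths = []
    for O in (10, 30, 100, 300):
        E = O / ratio
        n_event = int(round(E * 100))
        table = ContingencyTable(O=O, n_drug=max(O, 1000), n_event=max(O, n_event), N=100_000)
        # fix E via direct construction when margins cannot express it exactly
        res = information_component(table)
        widths.append(res.ic975 - res.ic025)
    assert widths == sorted(widths, reverse=True)


@pytest.mark.parametrize(
    "table",
    [
        ContingencyTable(O=8, n_drug=40, n_event=50, N=1000),
        ContingencyTable(O=2, n_drug=50, n_event=200, N=1000),
    ],
)
def test_scaling_cells_converges_to_unshrunk_ratio(table):
    """Multiplying all four cells by k drives IC to log2(O/E), keeping its sign."""
    target = math.log2(table.O / table.expected)
    assert abs(information_component(table).ic) > 0.1
    sign = math.copysign(1.0, information_component(table).ic)
    gaps = []
    for k in (1, 10, 100):
        res = information_component(table.scaled(k))
        assert math.copysign(1.0, res.ic) == sign
        gaps.append(abs(res.ic - target))
    assert gaps == sorted(gaps, reverse=True)


# ---------------------------------------------------------------------------
# comparative and screening


def test_comparative_null_simulation_not_signal():
    """With no injected association the comparator-restricted IC sits near 0."""
    cfg = default_config(n_reports=2000, seed=5)
    import dataclasses

    store, _ = generate_store(dataclasses.replace(cfg, associations=()))
    spec = ComparativeSpec(
        event_query=TermQuery(level="PT", label="Headache"),
        drug_of_interest=DrugQuery(mode="ATC_PREFIX", value="N02CD"),
        comparator=DrugQuery(mode="ATC_PREFIX", value="N02CC"),
    )
    res = comparative_ic(store, spec)
    assert abs(res.ic) < 0.5
    assert not res.is_signal


def test_comparative_overlap_policies(term_dict, drug_dict):
    from pvsignal.icsr import DrugEntry, ReactionEntry, Report, ReportStore

    def rep(i, ingredients, pt):
        return Report(
            report_id=f"C{i}",
            drugs=tuple(DrugEntry(ingredient=x, role="suspected") for x in ingredients),
            reactions=(ReactionEntry(pt=pt),),
        )

    store = ReportStore(
        [
            rep(1, ["erenumab"], RAYNAUD),
            rep(2, ["erenumab", "sumatriptan"], "Headache"),  # both classes
            rep(3, ["sumatriptan"], RAYNAUD),
            rep(4, ["sumatriptan"], "Headache"),
            rep(5, ["paracetamol"], "Headache"),  # outside the scope entirely
        ],
        term_dict,
        drug_dict,
    )
    spec = ComparativeSpec(
        event_query=TermQuery(level="PT", label=RAYNAUD),
        drug_of_interest=DrugQuery(mode="ATC_PREFIX", value="N02CD"),
        comparator=DrugQuery(mode="ATC_PREFIX", value="N02CC"),
    )
    keep = comparative_ic(store, spec, overlap="keep")
    assert keep.table.N == 4 and keep.table.n_drug == 2  # co-exposed goes to interest
    excl = comparative_ic(store, spec, overlap="exclude")
    assert excl.table.N == 3 and excl.table.n_drug == 1
    # the four cells are disjoint and sum to N
    assert sum(keep.table.cells()) == keep.table.N


def test_comparative_rejects_overlapping_classes(hand_store):
    spec = ComparativeSpec(
        event_query=TermQuery(level="PT", label=RAYNAUD),
        drug_of_interest=DrugQuery(mode="ATC_PREFIX", value="N02C"),
        comparator=DrugQuery(mode="INGREDIENT_SET", value=frozenset({"sumatriptan"})),
    )
    with pytest.raises(ValidationError, match="overlap"):
        comparative_ic(hand_store, spec)


def test_screen_orders_by_ic025_and_keeps_zero_pairs(hand_store):
    drugs = [
        DrugQuery(mode="INGREDIENT_SET", value=frozenset({"erenumab"})),
        DrugQuery(mode="INGREDIENT_SET", value=frozenset({"topiramate"})),
    ]
    events = [TermQuery(level="PT", label=RAYNAUD), TermQuery(level="PT", label="Headache")]
    results = screen_all_pairs(hand_store, drugs, events)
    assert len(results) == 4
    ic025s = [r.ic025 for r in results]
    assert ic025s == sorted(ic025s, reverse=True)
    zero_pairs = [r for r in results if r.table.O == 0]
    assert zero_pairs  # pairs with no observed reports are retained
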