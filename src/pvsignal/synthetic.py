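"""Synthetic spontaneous-report data.

Access to the large pharmacovigilance databases (VigiBase, FAERS, Eudra-
Vigilance) is restricted, so every stage of the analysis is exercised on
synthetic individual case safety reports instead.  Three generators are
provided:

* :func:`generate_store` — a configurable stochastic simulator.  Each report
  draws suspected drugs independently from per-ingredient marginal
  probabilities and reaction terms from per-PT baselines; an *association*
  multiplies the baseline probability of one event term by ρ whenever any of
  its associated drugs is present (capped at 1), injecting a known
  drug–event signal whose large-sample information component is available in
  closed form as :class:`GroundTruth`.  Demographics, dates, doses,
  seriousness, outcomes and missingness follow the configured laws.

* :func:`study_fixture` — a deterministic case series (99 index cases plus
  background reports) whose descriptive summaries reproduce a published
  case-count pattern exactly: per-drug shares, demographics, seriousness,
  outcomes, time to onset and monthly doses.

* :func:`comparative_fixture` — a count-faithful skeleton store realizing an
  exact set of comparator-restricted 2×2 cell counts, for validating the
  comparative disproportionality computation against printed numbers.
"""

from __future__ import annotations

import datetime as _dt
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .errors import ValidationError
from .icsr import DrugEntry, ReactionEntry, Report, ReportStore
from .terminology import DrugDictionary, DrugRecord, TermDictionary, TermRecord

__all__ = [
    "Association",
    "SyntheticConfig",
    "GroundTruth",
    "GroundTruthEntry",
    "default_term_dictionary",
    "default_drug_dictionary",
    "default_config",
    "generate_store",
    "study_fixture",
    "comparative_fixture",
]

_VASO_HLT = "Peripheral Vasoconstriction, necrosis and vascular insufficiency"
_RAYNAUD = "Raynaud's phenomenon"


def default_term_dictionary() -> TermDictionary:
    """A compact MedDRA-style dictionary covering the terms the package uses."""
    vascular = [
        (_RAYNAUD, _VASO_HLT, "Vascular disorders"),
        ("Peripheral coldness", _VASO_HLT, "Vascular disorders"),
        ("Gangrene", _VASO_HLT, "Vascular disorders"),
        ("Skin necrosis", _VASO_HLT, "Vascular disorders"),
    ]
    other = [
        ("Headache", "Headaches NEC", "Nervous system disorders"),
        ("Migraine", "Migraine headaches", "Nervous system disorders"),
        ("Dizziness", "Neurological signs and symptoms NEC", "Nervous system disorders"),
        ("Paraesthesia", "Paraesthesias and dysaesthesias", "Nervous system disorders"),
        ("Nausea", "Nausea and vomiting symptoms", "Gastrointestinal disorders"),
        ("Vomiting", "Nausea and vomiting symptoms", "Gastrointestinal disorders"),
        ("Abdominal pain", "Gastrointestinal and abdominal pains", "Gastrointestinal disorders"),
        (
            "Constipation",
            "Gastrointestinal atonic and hypomotility disorders NEC",
            "Gastrointestinal disorders",
        ),
        (
            "Arthralgia",
            "Joint related signs and symptoms",
            "Musculoskeletal and connective tissue disorders",
        ),
        ("Alopecia", "Alopecias", "Skin and subcutaneous tissue disorders"),
        ("Rash", "Rashes, eruptions and exanthems NEC", "Skin and subcutaneous tissue disorders"),
        ("Pruritus", "Pruritus NEC", "Skin and subcutaneous tissue disorders"),
        (
            "Skin discoloration",
            "Pigmentation changes NEC",
            "Skin and subcutaneous tissue disorders",
        ),
        (
            "Condition aggravated",
            "General signs and symptoms NEC",
            "General disorders and administration site conditions",
        ),
        (
            "Fatigue",
            "Asthenic conditions",
            "General disorders and administration site conditions",
        ),
        (
            "Injection site reaction",
            "Injection site reactions",
            "General disorders and administration site conditions",
        ),
        ("Weight increased", "Weight and body mass analyses", "Investigations"),
        ("Insomnia", "Disturbances in initiating and maintaining sleep", "Psychiatric disorders"),
    ]
    return TermDictionary(TermRecord(pt, hlt, soc) for pt, hlt, soc in vascular + other)


def default_drug_dictionary() -> DrugDictionary:
    """Ingredient → ATC mapping for the drug classes the analysis compares.

    N02CD (CGRP antagonists), N02CC (the 5HT1_B/D agonists a.k.a. triptans)
    and the beta-blockers used in migraine prophylaxis, plus a few common
    background drugs.
    """
    rows = [
        ("erenumab", "N02CD01"),
        ("galcanezumab", "N02CD02"),
        ("fremanezumab", "N02CD03"),
        ("ubrogepant", "N02CD04"),
        ("eptinezumab", "N02CD05"),
        ("rimegepant", "N02CD06"),
        ("atogepant", "N02CD07"),
        ("telcagepant", "N02CD08"),
        ("olcegepant", "N02CD09"),
        ("vazegepant", "N02CD10"),
        ("sumatriptan", "N02CC01"),
        ("naratriptan", "N02CC02"),
        ("zolmitriptan", "N02CC03"),
        ("rizatriptan", "N02CC04"),
        ("almotriptan", "N02CC05"),
        ("eletriptan", "N02CC06"),
        ("frovatriptan", "N02CC07"),
        ("propranolol", "C07AA05"),
        ("timolol", "C07AA06"),
        ("nadolol", "C07AA12"),
        ("metoprolol", "C07AB02"),
        ("atenolol", "C07AB03"),
        ("amitriptyline", "N06AA09"),
        ("topiramate", "N03AX11"),
        ("paracetamol", "N02BE01"),
        ("ibuprofen", "M01AE01"),
    ]
    return DrugDictionary(
        DrugRecord(ingredient=ing, atc_codes=frozenset({code})) for ing, code in rows
    )


@dataclass(frozen=True)
class Association:
    """Inject a drug–event signal: P(event | any drug present) = min(1, ρ·baseline)."""

    drugs: tuple[str, ...]
    pt: str
    rho: float


@dataclass(frozen=True)
class GroundTruthEntry:
    drugs: tuple[str, ...]
    pt: str
    rho: float
    p_conditional: float  # event probability when an associated drug is present
    p_marginal: float  # event probability over the whole generated population
    implied_ic: float  # log2(p_conditional / p_marginal), the large-sample IC

    def to_dict(self) -> dict:
        return {
            "drugs": list(self.drugs),
            "pt": self.pt,
            "rho": self.rho,
            "p_conditional": self.p_conditional,
            "p_marginal": self.p_marginal,
            "implied_ic": self.implied_ic,
        }


@dataclass(frozen=True)
class GroundTruth:
    """Closed-form targets for the injected associations of one simulation."""

    entries: tuple[GroundTruthEntry, ...]

    def for_pt(self, pt: str) -> GroundTruthEntry:
        for e in self.entries:
            if e.pt == pt:
                return e
        raise KeyError(pt)

    def to_dict(self) -> dict:
        return {"associations": [e.to_dict() for e in self.entries]}


#: seriousness criterion mix used for serious reports (fixed editorial choice)
_CRITERIA_CHOICES = ("hospitalization", "disabling", "other_medically_important")
_CRITERIA_PROBS = (0.5, 0.3, 0.2)

#: per-ingredient monthly maintenance doses the dose sampler draws from (mg)
_DOSE_CHOICES: Mapping[str, tuple[float, ...]] = {
    "erenumab": (70.0, 140.0),
    "galcanezumab": (120.0, 240.0),
    "fremanezumab": (225.0,),
}
_DOSE_DEFAULT = (25.0, 50.0, 100.0)


@dataclass(frozen=True)
class SyntheticConfig:
    """Generative parameters of the report simulator.

    Probability maps (`outcome_probs`, `country_probs`, `reporter_probs` and
    the age/sex parameters) must be proper distributions; drug and event
    marginals are independent per-report Bernoulli probabilities and need
    not sum to one.
    """

    n_reports: int
    seed: int
    drug_marginals: Mapping[str, float]
    event_marginals: Mapping[str, float]
    associations: tuple[Association, ...] = ()
    sex_p_female: float = 0.75
    age_law: tuple[str, Mapping[str, float]] = (
        "normal",
        {"mean": 48.0, "sd": 16.0, "min": 18.0, "max": 90.0},
    )
    tto_law: tuple[float, float] = (math.log(84.0), 2.25)  # (μ, σ) in log-days
    outcome_probs: Mapping[str, float] = field(
        default_factory=lambda: {
            "recovered": 0.28,
            "recovering": 0.06,
            "not_recovered": 0.64,
            "fatal": 0.02,
        }
    )
    serious_p: float = 0.152
    country_probs: Mapping[str, float] = field(
        default_factory=lambda: {
            "United States of America": 0.63,
            "Italy": 0.10,
            "Germany": 0.05,
            "Spain": 0.04,
            "Ireland": 0.04,
            "Netherlands": 0.04,
            "Belgium": 0.02,
            "Switzerland": 0.02,
            "Norway": 0.02,
            "Austria": 0.01,
            "United Kingdom": 0.01,
            "Iceland": 0.01,
            "Sweden": 0.01,
        }
    )
    reporter_probs: Mapping[str, float] = field(
        default_factory=lambda: {
            "physician": 0.51,
            "pharmacist": 0.03,
            "other_health_professional": 0.16,
            "consumer": 0.29,
            "lawyer": 0.01,
        }
    )
    missingness: Mapping[str, float] = field(
        default_factory=lambda: {
            "age_years": 0.41,
            "sex": 0.07,
            "country": 0.0,
            "outcome": 0.53,
            "onset_date": 0.35,
            "start_date": 0.35,
            "dose": 0.55,
            "drug_withdrawn": 0.31,
        }
    )

    def validate(self) -> None:
        """Raise :class:`ValidationError` listing every offending field."""
        bad: list[str] = []
        if not (isinstance(self.n_reports, int) and self.n_reports > 0):
            bad.append("n_reports")
        if not self.drug_marginals or not all(
            0 < p <= 1 for p in self.drug_marginals.values()
        ):
            bad.append("drug_marginals")
        if not self.event_marginals or not all(
            0 < p <= 1 for p in self.event_marginals.values()
        ):
            bad.append("event_marginals")
        for assoc in self.associations:
            if (
                assoc.rho < 0
                or assoc.pt not in self.event_marginals
                or not assoc.drugs
                or any(d not in self.drug_marginals for d in assoc.drugs)
            ):
                bad.append(f"associations[{assoc.pt}]")
        if not 0 <= self.sex_p_female <= 1:
            bad.append("sex_p_female")
        if self.age_law[0] not in ("normal", "uniform"):
            bad.append("age_law")
        if not 0 <= self.serious_p <= 1:
            bad.append("serious_p")
        for name, m in (
            ("outcome_probs", self.outcome_probs),
            ("country_probs", self.country_probs),
            ("reporter_probs", self.reporter_probs),
        ):
            if (
                not m
                or any(p < 0 for p in m.values())
                or abs(sum(m.values()) - 1.0) > 1e-9
            ):
                bad.append(name)
        if any(not 0 <= p <= 1 for p in self.missingness.values()):
            bad.append("missingness")
        if bad:
            raise ValidationError(f"invalid SyntheticConfig fields: {sorted(set(bad))}")


def default_config(n_reports: int = 20_000, seed: int = 0) -> SyntheticConfig:
    """Study-like defaults: migraine-treatment drug marginals, one injected
    vasospasm signal on the CGRP monoclonal antibodies."""
    return SyntheticConfig(
        n_reports=n_reports,
        seed=seed,
        drug_marginals={
            "erenumab": 0.020,
            "galcanezumab": 0.012,
            "fremanezumab": 0.008,
            "rimegepant": 0.003,
            "ubrogepant": 0.002,
            "sumatriptan": 0.080,
            "rizatriptan": 0.030,
            "propranolol": 0.060,
            "metoprolol": 0.040,
            "atenolol": 0.030,
            "paracetamol": 0.300,
            "ibuprofen": 0.200,
            "amitriptyline": 0.100,
            "topiramate": 0.080,
        },
        event_marginals={
            _RAYNAUD: 0.004,
            "Peripheral coldness": 0.003,
            "Headache": 0.12,
            "Migraine": 0.05,
            "Nausea": 0.10,
            "Dizziness": 0.08,
            "Fatigue": 0.07,
            "Rash": 0.06,
            "Vomiting": 0.05,
            "Arthralgia": 0.04,
            "Alopecia": 0.02,
            "Constipation": 0.03,
            "Condition aggravated": 0.02,
            "Skin discoloration": 0.01,
            "Weight increased": 0.02,
            "Injection site reaction": 0.04,
            "Paraesthesia": 0.03,
            "Insomnia": 0.04,
            "Pruritus": 0.04,
            "Abdominal pain": 0.05,
        },
        associations=(
            Association(
                drugs=("erenumab", "galcanezumab", "fremanezumab"),
                pt=_RAYNAUD,
                rho=8.0,
            ),
        ),
    )


def _p_drug_present(config: SyntheticConfig, drugs: Sequence[str]) -> float:
    """P(any drug of the set present) in the generated population.

    Drug indicators are independent, but zero-drug reports are redrawn, so
    the population is conditioned on at least one drug being present:
    P(any in S | ≥1 drug) = (1 − Π_{d∈S}(1−p_d)) / (1 − Π_{all d}(1−p_d)).
    """
    p_any_raw = 1.0 - math.prod(1.0 - config.drug_marginals[d] for d in drugs)
    p_nonempty = 1.0 - math.prod(1.0 - p for p in config.drug_marginals.values())
    return p_any_raw / p_nonempty


def ground_truth_of(config: SyntheticConfig) -> GroundTruth:
    """Closed-form conditional/marginal event probabilities and implied IC.

    For an association (drug set S, event e, ρ): P(e | any drug in S) =
    min(1, ρ·baseline), and the population marginal mixes the two exposure
    strata with the redraw-adjusted weight :func:`_p_drug_present`.  The
    implied IC is log2 of conditional over marginal.  The analogous redraw
    of zero-reaction reports is not corrected for; its effect on the ratio
    is second order at realistic event marginals.
    """
    entries = []
    for assoc in config.associations:
        base = config.event_marginals[assoc.pt]
        cond = min(1.0, assoc.rho * base)
        p_any = _p_drug_present(config, assoc.drugs)
        marginal = p_any * cond + (1.0 - p_any) * base
        entries.append(
            GroundTruthEntry(
                drugs=assoc.drugs,
                pt=assoc.pt,
                rho=assoc.rho,
                p_conditional=cond,
                p_marginal=marginal,
                implied_ic=math.log2(cond / marginal) if cond > 0 else float("-inf"),
            )
        )
    return GroundTruth(entries=tuple(entries))


def rho_for_implied_ic(
    config: SyntheticConfig, drugs: Sequence[str], pt: str, target_ic: float
) -> float:
    """Multiplier ρ whose large-sample implied IC equals ``target_ic``.

    Inverts the :func:`ground_truth_of` relation R = ρ / (1 + q(ρ − 1)),
    with R = 2^target_ic and q the redraw-adjusted exposure probability;
    requires R·q < 1 and no clipping of ρ·baseline at 1.
    """
    q = _p_drug_present(config, drugs)
    R = 2.0**target_ic
    if R * q >= 1.0:
        raise ValidationError(
            f"target IC {target_ic} unreachable at exposure probability {q:.4f}"
        )
    rho = R * (1.0 - q) / (1.0 - R * q)
    if rho * config.event_marginals[pt] > 1.0:
        raise ValidationError("implied conditional probability exceeds 1")
    return rho


def generate_store(
    config: SyntheticConfig,
) -> tuple[ReportStore, GroundTruth]:
    """Draw a synthetic report store; deterministic given ``config.seed``.

    Reports that draw zero drugs or zero reactions are redrawn (not
    dropped), so the store size equals ``n_reports`` exactly.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    n = config.n_reports

    drug_names = list(config.drug_marginals)
    p_drug = np.array([config.drug_marginals[d] for d in drug_names])
    event_names = list(config.event_marginals)
    p_event = np.array([config.event_marginals[e] for e in event_names])
    event_col = {e: j for j, e in enumerate(event_names)}
    drug_col = {d: j for j, d in enumerate(drug_names)}

    # suspected-drug indicators, redrawing empty rows so every report has >=1 drug
    X = rng.random((n, len(drug_names))) < p_drug
    empty = ~X.any(axis=1)
    while empty.any():
        X[empty] = rng.random((int(empty.sum()), len(drug_names))) < p_drug
        empty = ~X.any(axis=1)

    # per-row event probabilities with association multipliers applied
    P = np.tile(p_event, (n, 1))
    for assoc in config.associations:
        mask = X[:, [drug_col[d] for d in assoc.drugs]].any(axis=1)
        P[mask, event_col[assoc.pt]] = min(1.0, assoc.rho * p_event[event_col[assoc.pt]])
    Y = rng.random((n, len(event_names))) < P
    empty = ~Y.any(axis=1)
    while empty.any():
        idx = np.flatnonzero(empty)
        Y[idx] = rng.random((len(idx), len(event_names))) < P[idx]
        empty = ~Y.any(axis=1)

    # demographics and report-level attributes (vectorized draws)
    sex = np.where(rng.random(n) < config.sex_p_female, "female", "male")
    family, pars = config.age_law
    if family == "normal":
        age = rng.normal(pars["mean"], pars["sd"], n)
    else:
        age = rng.uniform(pars["min"], pars["max"], n)
    age = np.clip(np.rint(age), pars.get("min", 0.0), pars.get("max", 120.0))
    countries = list(config.country_probs)
    country = rng.choice(countries, n, p=[config.country_probs[c] for c in countries])
    reporters = list(config.reporter_probs)
    reporter = rng.choice(reporters, n, p=[config.reporter_probs[r] for r in reporters])
    outcomes = list(config.outcome_probs)
    outcome = rng.choice(outcomes, n, p=[config.outcome_probs[o] for o in outcomes])
    serious = rng.random(n) < config.serious_p
    serious |= outcome == "fatal"  # a fatal outcome is serious by definition
    criteria = rng.choice(_CRITERIA_CHOICES, n, p=_CRITERIA_PROBS)
    withdrawn = rng.random(n) < 0.33
    start_offset = rng.integers(0, 1095, n)  # reporting window ~3 years
    mu, sigma = config.tto_law
    tto_days = np.rint(rng.lognormal(mu, sigma, n)).astype(int)

    miss = {
        fld: rng.random(n) < config.missingness.get(fld, 0.0)
        for fld in (
            "age_years",
            "sex",
            "country",
            "outcome",
            "onset_date",
            "start_date",
            "dose",
            "drug_withdrawn",
        )
    }
    dose_pick = rng.random(n)  # one uniform per report reused across its drugs

    base_date = _dt.date(2019, 1, 1)
    reports: list[Report] = []
    for i in range(n):
        start = (
            None
            if miss["start_date"][i]
            else base_date + _dt.timedelta(days=int(start_offset[i]))
        )
        onset = (
            None
            if (miss["onset_date"][i] or start is None)
            else start + _dt.timedelta(days=int(tto_days[i]))
        )
        drugs = []
        for j in np.flatnonzero(X[i]):
            name = drug_names[j]
            if miss["dose"][i]:
                amount = None
            else:
                choices = _DOSE_CHOICES.get(name, _DOSE_DEFAULT)
                amount = choices[int(dose_pick[i] * len(choices)) % len(choices)]
            drugs.append(
                DrugEntry(
                    ingredient=name,
                    role="suspected",
                    dose_amount=amount,
                    dose_unit="mg" if amount is not None else None,
                    dose_interval_days=30.0 if amount is not None else None,
                    start_date=start,
                    indication="Migraine prophylaxis" if start is not None else None,
                )
            )
        reactions = []
        first = True
        for j in np.flatnonzero(Y[i]):
            if first:
                is_fatal = outcome[i] == "fatal" and not miss["outcome"][i]
                reactions.append(
                    ReactionEntry(
                        pt=event_names[j],
                        onset_date=onset,
                        serious=bool(serious[i]),
                        seriousness_criteria=(
                            frozenset(
                                {"death" if is_fatal else str(criteria[i])}
                            )
                            if serious[i]
                            else frozenset()
                        ),
                        outcome=None if miss["outcome"][i] else str(outcome[i]),
                    )
                )
                first = False
            else:
                reactions.append(ReactionEntry(pt=event_names[j], onset_date=onset))
        reports.append(
            Report(
                report_id=f"SR-{i + 1:07d}",
                country=None if miss["country"][i] else str(country[i]),
                reporter_qualifications=(str(reporter[i]),),
                sex=None if miss["sex"][i] else str(sex[i]),
                age_years=None if miss["age_years"][i] else float(age[i]),
                drug_withdrawn=None if miss["drug_withdrawn"][i] else bool(withdrawn[i]),
                drugs=tuple(drugs),
                reactions=tuple(reactions),
            )
        )
    store = ReportStore(
        reports, default_term_dictionary(), default_drug_dictionary()
    )
    return store, ground_truth_of(config)


# ---------------------------------------------------------------------------
# deterministic fixtures


def _study_ages() -> list[float]:
    """58 documented ages: bands 29/27/2, median 45, IQR 35-57, range 20-70."""
    band1 = [20, 22, 25, 27, 28, 30, 31, 32, 33, 34, 34, 35, 35, 35, 35, 35,
             36, 37, 38, 39, 40, 40, 41, 42, 42, 43, 43, 44, 44]
    band2 = [46, 47, 48, 49, 50, 51, 52, 53, 54, 55, 56, 56, 57, 57, 57,
             58, 59, 60, 61, 62, 63, 63, 64, 64, 64, 64, 64]
    band3 = [65, 70]
    return [float(a) for a in band1 + band2 + band3]


def study_fixture(n_background: int = 300) -> ReportStore:
    """A deterministic 99-case vasospasm series plus background reports.

    The 99 index cases carry a CGRP-antagonist suspect drug and the index
    event, with drug shares 56/28/13/1/1 (erenumab / galcanezumab /
    fremanezumab / ubrogepant / rimegepant), 86 female of 93 documented, age
    bands 29/27/2 of 58 documented, 15 serious (6 disabling), outcomes
    31/3/13 among 47 documented, withdrawal 23 of 68 documented, times to
    onset with median 84 days (IQR 18-383) and class-typical monthly doses.
    Background reports involve comparator and unrelated drugs so that
    contingency tables on the fixture are non-degenerate.
    """
    case_drug = (
        ["erenumab"] * 56 + ["galcanezumab"] * 28 + ["fremanezumab"] * 13
        + ["ubrogepant"] + ["rimegepant"]
    )
    countries = (
        ["United States of America"] * 62 + ["Italy"] * 10 + ["Germany"] * 5
        + ["Spain"] * 4 + ["Ireland"] * 4 + ["Netherlands"] * 4 + ["Belgium"] * 2
        + ["Switzerland"] * 2 + ["Norway"] * 2 + ["Austria"] + ["United Kingdom"]
        + ["Iceland"] + ["Sweden"]
    )
    ages = _study_ages()
    coreported = {
        "Arthralgia": range(1, 8),
        "Alopecia": range(8, 13),
        "Condition aggravated": range(13, 18),
        "Constipation": range(18, 22),
        "Fatigue": range(22, 26),
        "Skin discoloration": range(26, 30),
        "Weight increased": range(30, 34),
    }
    cosuspects = {"propranolol": range(1, 4), "rizatriptan": range(4, 6), "nadolol": range(6, 8)}
    tto = {1: 18, 2: 18, 3: 84, 4: 383, 5: 383}
    dose = {1: 70.0, 2: 70.0, 3: 140.0, 57: 120.0, 58: 120.0, 59: 240.0, 85: 225.0}
    start0 = _dt.date(2020, 1, 1)

    reports: list[Report] = []
    for k in range(1, 100):
        start = start0 if k in tto else None
        entries = [
            DrugEntry(
                ingredient=case_drug[k - 1],
                role="suspected",
                dose_amount=dose.get(k),
                dose_unit="mg" if k in dose else None,
                dose_interval_days=30.0 if k in dose else None,
                start_date=start,
                indication="Migraine prophylaxis",
            )
        ]
        for ing, rng_ in cosuspects.items():
            if k in rng_:
                entries.append(DrugEntry(ingredient=ing, role="suspected"))
        serious = k <= 15
        criteria = (
            frozenset({"disabling"})
            if k <= 6
            else frozenset({"other_medically_important"})
            if serious
            else frozenset()
        )
        if k <= 31:
            outcome = "not_recovered"
        elif k <= 34:
            outcome = "recovering"
        elif k <= 47:
            outcome = "recovered"
        else:
            outcome = None
        reactions = [
            ReactionEntry(
                pt=_RAYNAUD,
                onset_date=(start0 + _dt.timedelta(days=tto[k])) if k in tto else None,
                serious=serious,
                seriousness_criteria=criteria,
                outcome=outcome,
            )
        ]
        for pt, rng_ in coreported.items():
            if k in rng_:
                reactions.append(ReactionEntry(pt=pt))
        if k == 1:  # the narrative ischaemic-complication case
            reactions.append(ReactionEntry(pt="Gangrene"))
            reactions.append(ReactionEntry(pt="Skin necrosis"))
        reports.append(
            Report(
                report_id=f"CASE-{k:03d}",
                country=countries[k - 1],
                reporter_qualifications=_fixture_reporters(k),
                sex="female" if k <= 86 else "male" if k <= 93 else None,
                age_years=ages[k - 1] if k <= 58 else None,
                drug_withdrawn=True if k <= 23 else False if k <= 68 else None,
                drugs=tuple(entries),
                reactions=tuple(reactions),
            )
        )

    bg_drugs = ["sumatriptan", "propranolol", "amitriptyline", "topiramate",
                "paracetamol", "ibuprofen"]
    bg_events = ["Headache", "Migraine", "Nausea", "Dizziness", "Fatigue", "Insomnia"]
    for k in range(1, n_background + 1):
        if k <= 5:
            drug, pt = "sumatriptan", _RAYNAUD
        elif k <= 11:
            drug, pt = "propranolol", _RAYNAUD
        elif k <= 14:
            drug, pt = "sumatriptan", "Peripheral coldness"
        else:
            drug = bg_drugs[k % len(bg_drugs)]
            pt = bg_events[(k // len(bg_drugs)) % len(bg_events)]
        reports.append(
            Report(
                report_id=f"BG-{k:04d}",
                drugs=(DrugEntry(ingredient=drug, role="suspected"),),
                reactions=(ReactionEntry(pt=pt),),
            )
        )
    return ReportStore(reports, default_term_dictionary(), default_drug_dictionary())


def _fixture_reporters(k: int) -> tuple[str, ...]:
    """Qualification pattern summing to 51/3/16/39 over the 99 cases."""
    if k <= 3:
        return ("physician", "pharmacist")
    if k <= 10:
        return ("physician", "consumer")
    if k <= 51:
        return ("physician",)
    if k <= 67:
        return ("other_health_professional",)
    return ("consumer",)


def comparative_fixture() -> ReportStore:
    """A count-faithful skeleton store for the comparator-restricted analysis.

    Realizes exactly the cell pattern: 99 index-event reports and 55,506
    other-event reports with the CGRP class; 43 index-event and 47,417
    other-event reports with the triptan class; 142 index-event and 129,222
    other-event reports with the beta-blocker class.  Every report carries a
    single suspected drug and a single reaction, so the comparator-restricted
    2×2 tables reproduce those counts identically.
    """
    blocks = [
        ("CG-RP", "erenumab", _RAYNAUD, 99),
        ("CG-OT", "erenumab", "Headache", 55_506),
        ("TR-RP", "sumatriptan", _RAYNAUD, 43),
        ("TR-OT", "sumatriptan", "Headache", 47_417),
        ("BB-RP", "propranolol", _RAYNAUD, 142),
        ("BB-OT", "propranolol", "Headache", 129_222),
    ]
    reports: list[Report] = []
    for prefix, ingredient, pt, count in blocks:
        drug_entry = (DrugEntry(ingredient=ingredient, role="suspected"),)
        reaction = (ReactionEntry(pt=pt),)
        reports.extend(
            Report(report_id=f"{prefix}-{i:06d}", drugs=drug_entry, reactions=reaction)
            for i in range(1, count + 1)
        )
    return ReportStore(reports, default_term_dictionary(), default_drug_dictionary())
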