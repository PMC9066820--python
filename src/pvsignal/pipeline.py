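"""End-to-end study replication: load or simulate, query, analyse, report.

`run_study` drives the full analysis for one event/drug-class question:
case listing, descriptive tables, the per-class and per-drug information
component screen, the HLT-level sensitivity analysis, and one comparator-
restricted IC per comparator class.  Outputs are TSV tables plus a single
machine-readable ``study_report.json`` and a run manifest.  A self-
consistency pass at the end recomputes every percentage and IC in the
report from the emitted counts.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

import yaml

from . import __version__
from ._util import round_half_up
from .errors import PvSignalError, ValidationError
from .descriptives import (
    categorical_summary,
    coreported_terms,
    outcome_summary,
    quantitative_summary,
)
from .disprop import (
    ComparativeSpec,
    ContingencyTable,
    ICResult,
    comparative_ic,
    information_component,
    screen_all_pairs,
)
from .icsr import ReportStore, load_reports, match_reports, monthly_dose, time_to_onset
from .synthetic import (
    SyntheticConfig,
    Association,
    comparative_fixture,
    default_config,
    generate_store,
    study_fixture,
)
from .terminology import (
    DrugDictionary,
    DrugQuery,
    TermDictionary,
    TermQuery,
    expand_drug_query,
    normalize_label,
)

__all__ = ["StudyConfig", "run_study", "verify_study_report", "load_synthetic_config"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class StudyConfig:
    """One study run: a data source, an event query, drug classes, options.

    Exactly one data source must be given: the three report tables plus the
    two dictionaries (``data_paths``), a simulation config (``simulate``),
    or a named built-in fixture (``fixture``: "study" or "comparative").
    """

    event_pt: str | None = None
    event_hlt: str | None = None
    drug_atc: str = "N02CD"
    comparator_atc: tuple[str, ...] = ()
    ci_method: Literal["gamma_quantile", "noren_approx"] = "gamma_quantile"
    overlap: Literal["keep", "exclude"] = "keep"
    data_paths: Mapping[str, str] | None = None  # reports/drugs/reactions/meddra/atc
    simulate: SyntheticConfig | None = None
    fixture: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        sources = [
            self.data_paths is not None,
            self.simulate is not None,
            self.fixture is not None,
        ]
        if sum(sources) != 1:
            raise ValidationError(
                "exactly one data source (data_paths, simulate, fixture) is required"
            )
        if (self.event_pt is None) == (self.event_hlt is None):
            raise ValidationError("exactly one of event_pt / event_hlt is required")
        if self.fixture is not None and self.fixture not in ("study", "comparative"):
            raise ValidationError(f"unknown fixture {self.fixture!r}")

    @property
    def event_query(self) -> TermQuery:
        if self.event_pt is not None:
            return TermQuery(level="PT", label=self.event_pt)
        assert self.event_hlt is not None
        return TermQuery(level="HLT", label=self.event_hlt)

    def digest(self) -> str:
        payload = {
            "event_pt": self.event_pt,
            "event_hlt": self.event_hlt,
            "drug_atc": self.drug_atc,
            "comparator_atc": list(self.comparator_atc),
            "ci_method": self.ci_method,
            "overlap": self.overlap,
            "data_paths": dict(self.data_paths) if self.data_paths else None,
            "fixture": self.fixture,
            "seed": self.seed,
        }
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]


def load_synthetic_config(path: str | Path) -> SyntheticConfig:
    """Read a simulation config from a YAML key/value file."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    assoc_raw = raw.pop("associations", None)
    age_law = raw.pop("age_law", None)
    kwargs = dict(raw)
    if assoc_raw is not None:  # an explicit empty list means "no associations"
        kwargs["associations"] = tuple(
            Association(drugs=tuple(a["drugs"]), pt=a["pt"], rho=float(a["rho"]))
            for a in assoc_raw
        )
    if age_law is not None:
        kwargs["age_law"] = (age_law[0], dict(age_law[1]))
    tto = kwargs.pop("tto_law", None)
    if tto is not None:
        kwargs["tto_law"] = (float(tto[0]), float(tto[1]))
    base = default_config(
        n_reports=kwargs.pop("n_reports", 20_000), seed=kwargs.pop("seed", 0)
    )
    cfg = SyntheticConfig(
        n_reports=base.n_reports,
        seed=base.seed,
        drug_marginals=kwargs.pop("drug_marginals", base.drug_marginals),
        event_marginals=kwargs.pop("event_marginals", base.event_marginals),
        associations=kwargs.pop("associations", base.associations),
        **kwargs,
    )
    cfg.validate()
    return cfg


def _obtain_store(config: StudyConfig) -> ReportStore:
    if config.fixture == "study":
        return study_fixture()
    if config.fixture == "comparative":
        return comparative_fixture()
    if config.simulate is not None:
        store, _ = generate_store(config.simulate)
        return store
    assert config.data_paths is not None
    required = {"reports", "drugs", "reactions", "meddra", "atc"}
    missing = required - set(config.data_paths)
    if missing:
        raise ValidationError(f"data_paths missing entries: {sorted(missing)}")
    return load_reports(
        config.data_paths["reports"],
        config.data_paths["drugs"],
        config.data_paths["reactions"],
        TermDictionary.from_csv(config.data_paths["meddra"]),
        DrugDictionary.from_csv(config.data_paths["atc"]),
    )


def _write_tsv(path: Path, header: Sequence[str], rows: Sequence[Sequence]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join("" if v is None else str(v) for v in row) + "\n")


def _summary_payload(table) -> dict:
    return {
        "denominator": table.denominator,
        "denominator_rule": table.denominator_rule,
        "rows": table.to_records(),
    }


def run_study(config: StudyConfig, outdir: str | Path) -> dict:
    """Execute the full analysis and write the study report under ``outdir``.

    Returns the study-report dictionary (also written as JSON).  On any
    stage failure a ``FAILED`` marker naming the stage is left in the output
    directory and the exception propagates.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    try:
        store = _obtain_store(config)
        stage = "query"
        event_q = config.event_query
        class_q = DrugQuery(mode="ATC_PREFIX", value=config.drug_atc)
        case_ids = sorted(match_reports(store, term_query=event_q, drug_query=class_q))
        if not case_ids:
            logger.warning("no case reports matched the event/drug query")
        _write_tsv(
            outdir / "cases.tsv",
            ["report_id", "suspected_drugs", "sex", "age_years", "country", "serious", "outcome"],
            [
                (
                    rid,
                    ";".join(sorted({d.ingredient for d in store.get(rid).drugs})),
                    store.get(rid).sex,
                    store.get(rid).age_years,
                    store.get(rid).country,
                    store.get(rid).serious,
                    store.get(rid).outcome,
                )
                for rid in case_ids
            ],
        )

        stage = "descriptives"
        descr = _descriptives(store, case_ids, event_q, class_q, outdir)

        stage = "disproportionality"
        screen = _screen(store, event_q, class_q, config)
        _write_tsv(
            outdir / "ic_screen.tsv",
            ["drug", "event", "O", "n_drug", "n_event", "N", "E", "ic", "ic025", "ic975", "signal"],
            [
                (
                    r.drug_label,
                    r.event_label,
                    r.table.O,
                    r.table.n_drug,
                    r.table.n_event,
                    r.table.N,
                    round_half_up(r.E, 1),
                    *r.rounded(),
                    r.is_signal,
                )
                for r in screen["results"]
            ],
        )

        stage = "comparative"
        comparatives = []
        for atc in config.comparator_atc:
            spec = ComparativeSpec(
                event_query=event_q,
                drug_of_interest=class_q,
                comparator=DrugQuery(mode="ATC_PREFIX", value=atc),
            )
            res = comparative_ic(
                store, spec, ci_method=config.ci_method, overlap=config.overlap
            )
            comparatives.append({"comparator_atc": atc, **res.to_dict()})

        stage = "report"
        report = {
            "config": {
                "event": {"level": event_q.level, "label": event_q.label},
                "drug_atc": config.drug_atc,
                "comparator_atc": list(config.comparator_atc),
                "ci_method": config.ci_method,
                "overlap": config.overlap,
            },
            "n_reports_in_store": len(store),
            "n_cases": len(case_ids),
            "rejects": store.rejects.summary(),
            "descriptives": descr,
            "screen": [r.to_dict() for r in screen["results"]],
            "hlt_sensitivity": screen["hlt_sensitivity"],
            "comparative": comparatives,
            "manifest": {
                "package": "pvsignal",
                "version": __version__,
                "seed": config.seed,
                "config_digest": config.digest(),
            },
        }
        verify_study_report(report)
        with open(outdir / "study_report.json", "w", encoding="utf-8") as fh:
            json.dump(report, fh, indent=2)
        with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(report["manifest"], fh, indent=2)
        return report
    except Exception as exc:
        (outdir / "FAILED").write_text(f"stage={stage}: {exc}\n", encoding="utf-8")
        raise


def _descriptives(store, case_ids, event_q, class_q, outdir: Path) -> dict:
    index_pts = set()
    try:
        from .terminology import expand_term_query

        index_pts = expand_term_query(event_q, store.term_dict)
    except PvSignalError:
        pass
    tables = {
        "drug": categorical_summary(store, case_ids, "drug"),
        "sex": categorical_summary(store, case_ids, "sex", "known"),
        "age_band": categorical_summary(store, case_ids, "age_band", "known"),
        "country": categorical_summary(store, case_ids, "country"),
        "reporter_qualification": categorical_summary(
            store, case_ids, "reporter_qualification"
        ),
        "seriousness": categorical_summary(store, case_ids, "seriousness"),
        "outcome": outcome_summary(store, case_ids),
        "drug_withdrawn": categorical_summary(store, case_ids, "drug_withdrawn", "known"),
    }
    for name, table in tables.items():
        _write_tsv(
            outdir / f"descr_{name}.tsv",
            ["label", "count", "percent", "denominator", "rule"],
            [
                (r.label, r.count, r.percent, table.denominator, table.denominator_rule)
                for r in table.rows
            ],
        )
    quant: dict[str, dict] = {}
    ages = [store.get(rid).age_years for rid in case_ids]
    if any(a is not None for a in ages):
        quant["age_years"] = quantitative_summary(ages).to_dict()
    ttos = []
    for rid in case_ids:
        t = time_to_onset(
            store.get(rid), class_q, store.drug_dict,
            term_query=event_q, term_dict=store.term_dict,
        )
        if t is not None and not t.implausible:  # negatives excluded from summaries
            ttos.append(float(t.days))
    if ttos:
        quant["time_to_onset_days"] = quantitative_summary(ttos).to_dict()
    doses: dict[str, list[float]] = {}
    class_ings = {
        normalize_label(i) for i in expand_drug_query(class_q, store.drug_dict)
    }
    for rid in case_ids:
        for d in store.get(rid).drugs:
            if normalize_label(d.ingredient) in class_ings:
                md = monthly_dose(d)
                if md is not None:
                    doses.setdefault(d.ingredient, []).append(md)
    quant.update(
        {
            f"monthly_dose_mg[{ing}]": quantitative_summary(v).to_dict()
            for ing, v in sorted(doses.items())
        }
    )
    cor = coreported_terms(store, case_ids, exclude=index_pts or {event_q.label})
    _write_tsv(
        outdir / "descr_coreported.tsv",
        ["pt", "count", "percent"],
        cor[:20],
    )
    return {
        "categorical": {k: _summary_payload(t) for k, t in tables.items()},
        "quantitative": quant,
        "coreported_terms": [
            {"pt": p, "count": c, "percent": pc} for p, c, pc in cor[:20]
        ],
    }


def _screen(store, event_q, class_q, config: StudyConfig) -> dict:
    ingredients = sorted(expand_drug_query(class_q, store.drug_dict))
    drug_queries = [class_q] + [
        DrugQuery(mode="INGREDIENT_SET", value=frozenset({ing})) for ing in ingredients
    ]
    results = screen_all_pairs(store, drug_queries, [event_q], ci_method=config.ci_method)
    hlt_sensitivity = None
    if event_q.level == "PT":
        hlt = store.term_dict.hlt_of(event_q.label)
        from .disprop import build_table

        table = build_table(store, TermQuery(level="HLT", label=hlt), class_q)
        res = information_component(table, config.ci_method)
        hlt_sensitivity = {"hlt": hlt, **res.to_dict()}
    return {"results": results, "hlt_sensitivity": hlt_sensitivity}


def verify_study_report(report: dict) -> None:
    """Recompute every IC and percentage in a study report from its counts.

    Raises :class:`ValidationError` on the first inconsistency; called at
    the end of every run as a self-check.
    """
    def check_ic(rec: dict, where: str) -> None:
        table = ContingencyTable(
            O=int(rec["O"]), n_drug=int(rec["n_drug"]),
            n_event=int(rec["n_event"]), N=int(rec["N"]),
        )
        fresh = information_component(table, rec["ci_method"])
        for key in ("E", "ic", "ic025", "ic975"):
            if not math.isclose(getattr(fresh, key if key != "E" else "E"), rec[key], rel_tol=1e-12, abs_tol=1e-12):
                raise ValidationError(f"{where}: {key} does not recompute from cells")
        if fresh.is_signal != rec["is_signal"]:
            raise ValidationError(f"{where}: signal flag does not recompute")

    for i, rec in enumerate(report.get("screen", [])):
        check_ic(rec, f"screen[{i}]")
    for i, rec in enumerate(report.get("comparative", [])):
        check_ic(rec, f"comparative[{i}]")
    if report.get("hlt_sensitivity"):
        check_ic(report["hlt_sensitivity"], "hlt_sensitivity")
    for name, payload in report.get("descriptives", {}).get("categorical", {}).items():
        denom = payload["denominator"]
        for row in payload["rows"]:
            expected = round_half_up(100.0 * row["count"] / denom, 1) if denom else 0.0
            if row["percent"] != expected:
                raise ValidationError(
                    f"descriptives[{name}] {row['label']}: percent does not recompute"
                )
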