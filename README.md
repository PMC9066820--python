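# pvsignal

Case/non-case disproportionality analysis for spontaneous adverse-event
reports, built around the Bayesian **Information Component (IC)** used in
pharmacovigilance signal detection — with comparator-restricted analysis,
case-series descriptives, and a synthetic report simulator for validation.

## The problem

Spontaneous-reporting databases (VigiBase, FAERS, EudraVigilance) collect
individual case safety reports (ICSRs): one patient, one or more suspected
drugs, one or more reactions coded as MedDRA Preferred Terms (PTs).
Disproportionality analysis asks whether an event is reported with a drug
more often than the database as a whole would predict. The motivating use
case is vascular safety of CGRP-targeting migraine drugs (ATC class N02CD):
calcitonin gene-related peptide is a potent vasodilator, so blocking it may
precipitate Raynaud's phenomenon, an episodic vasospasm of the digits.
Because migraine patients are independently prone to Raynaud's phenomenon,
a naive whole-database comparison is confounded by indication; the analysis
is therefore repeated restricted to reports involving either the class of
interest or an active comparator used in the same population (triptans,
beta-blockers).

## The statistic

Reports reduce to a 2×2 table per drug–event pair: observed count `O`
(reports with both), margins `n_drug`, `n_event`, total `N`. With
`E = n_drug · n_event / N`, the shrunk information component is

```
IC    = log2( (O + 1/2) / (E + 1/2) )
IC025 = log2( q_0.025 of Gamma(shape = O + 1/2, rate = E + 1/2) )
IC975 = log2( q_0.975 of Gamma(shape = O + 1/2, rate = E + 1/2) )
```

`IC025 > 0` is the conventional signal threshold. A closed-form
approximation of the interval is provided as a cross-check
(`ci_method="noren_approx"`). The comparator-restricted IC applies the same
formula within the scope of reports involving either drug class, with
co-exposed reports assigned to the class of interest (configurable).

## Worked example

The built-in `comparative_fixture()` realizes a published cell pattern
exactly: 99 Raynaud's-phenomenon reports and 55,506 other-event reports
with CGRP antagonists, versus 43 and 47,417 with triptans:

```python
from pvsignal import (comparative_fixture, ComparativeSpec, TermQuery,
                      DrugQuery, comparative_ic)

store = comparative_fixture()
spec = ComparativeSpec(
    event_query=TermQuery(level="PT", label="Raynaud's phenomenon"),
    drug_of_interest=DrugQuery(mode="ATC_PREFIX", value="N02CD"),
    comparator=DrugQuery(mode="ATC_PREFIX", value="N02CC"),
)
res = comparative_ic(store, spec)
t = res.table
ic, lo, hi = res.rounded()
print(f"O={t.O}  n_drug={t.n_drug}  n_event={t.n_event}  N={t.N}  E={res.E:.2f}")
print(f"IC = {ic} (95% CrI {lo} to {hi})  signal: {res.is_signal}")
```

prints

```
O=99  n_drug=55605  n_event=142  N=103065  E=76.61
IC = 0.4 (95% CrI 0.1 to 0.6)  signal: True
```

Read: 99 reports pair the event with the class of interest where 76.6 were
expected under independence within the restricted scope — about 2^0.4 ≈ 1.3
times more than expected, and the entire credible interval sits above zero,
so the event remains disproportionately reported even against an active
comparator treating the same condition.

The same analysis is available from the shell:

```
pvsignal run-study --fixture comparative --event-pt "Raynaud's phenomenon" \
    --comparator-atc N02CC --comparator-atc C07A --out study/
```

which writes the case listing, descriptive tables, the per-drug IC screen,
the HLT-level sensitivity analysis and one comparative IC per comparator,
plus a machine-readable `study_report.json` whose every percentage and IC
is re-derived from its emitted counts before the run is declared clean.
`pvsignal simulate` generates synthetic report tables with a known injected
signal (`ground_truth.json` carries its closed-form implied IC) for
end-to-end testing without database access.

## Layout

- `src/pvsignal/terminology.py` — MedDRA-style PT/HLT/SOC and ATC
  dictionaries, query expansion
- `src/pvsignal/icsr.py` — ICSR data model, relational CSV loading,
  report-level matching, time to onset, dose normalization
- `src/pvsignal/disprop.py` — contingency tables, IC and credible
  intervals, comparative IC, pair screening
- `src/pvsignal/descriptives.py` — case-series tables with explicit
  denominators, median/IQR summaries, co-reported term ranking
- `src/pvsignal/synthetic.py` — report simulator with closed-form ground
  truth; deterministic study and comparative fixtures
- `src/pvsignal/pipeline.py`, `cli.py` — the `pvsignal` command

See `docs/methods.md` for the statistical model, conventions and
limitations.
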