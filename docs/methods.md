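# Methods

## Data model and counting semantics

An individual case safety report (ICSR) carries administrative fields
(country, reporter qualification), patient fields (sex, age), one or more
drug entries (ingredient, role among suspected/interacting/concomitant,
dose, administration dates, indication) and one or more reaction entries
(MedDRA-style Preferred Term, onset date, seriousness, outcome). Reports
arrive as three relational CSV tables keyed by `report_id`; rows that do
not validate are collected in a reject log with reasons — never silently
dropped — because missingness and rejects are themselves findings in
pharmacovigilance data.

All counting is **report-level**: a report contributes at most one to any
cell no matter how many of its drug or reaction entries match a query. A
report matches an event query if any reaction PT is in the expanded PT set
(a PT query expands to itself; an HLT query expands to all PTs filed under
the High Level Term, single-path assignment assumed). It matches a drug
query if any drug entry has an ingredient in the expanded set (ATC prefix
or explicit ingredient list) *and* a role in the query's role filter. The
default role filter is suspected + interacting: purely concomitant drugs do
not generate observed counts, the usual convention for attributing
suspected reactions. Labels match case-insensitively after whitespace
normalization, with typographic apostrophes folded to ASCII, since
reporting sources are inconsistent in both.

## The information component

For a drug–event pair the reports in scope reduce to a 2×2 table
(`O`, `n_drug`, `n_event`, `N`) with expected count
`E = n_drug · n_event / N`. The point estimate is the shrunk log ratio

    IC = log2((O + 1/2) / (E + 1/2)),

the additive 1/2 pulling small-count estimates toward zero. The 95%
credible interval treats `O` as Poisson with a gamma posterior:
`IC025`/`IC975` are log2 of the 2.5% / 97.5% quantiles of
Gamma(shape `O + 1/2`, rate `E + 1/2`), evaluated with scipy's gamma
quantile function and cross-checked in the test suite against direct
numerical integration of the posterior density. A closed-form
approximation

    IC025 ≈ IC − 3.3·(O+1/2)^(−1/2) − 2.0·(O+1/2)^(−3/2)
    IC975 ≈ IC + 2.4·(O+1/2)^(−1/2) − 0.5·(O+1/2)^(−3/2)

is exposed as `ci_method="noren_approx"`; the two lower bounds agree within
0.15 bits for `O ≥ 10` over the grid `O ∈ {10, 30, 100, 300}`,
`E/O ∈ {0.5, 1, 2}` (asserted in the suite). `IC025 > 0` flags a signal;
no multiple-testing adjustment is applied across screened pairs, matching
signal-detection practice where the per-pair threshold is the convention.
The shrinkage constant and the gamma-quantile interval are the canonical
published formulation; production systems differ in detail, which is why
both interval variants are tagged in every result and displayed values are
rounded half-up to one decimal (full precision is retained in machine
output). Screening output is ordered by IC025 descending, ties by `O`
descending then labels lexicographically, and pairs with `O = 0` are
retained: an absence of reports is information.

## Comparator-restricted (comparative) disproportionality

Whole-database disproportionality confounds drug and indication whenever
the event is associated with the treated condition. The comparative IC
restricts the scope to reports involving either the class of interest or a
comparator class used in the same population, then computes the same
statistic with the class of interest as the exposure. The two classes must
expand to disjoint ingredient sets; reports carrying drugs from both are
assigned to the class-of-interest row by default (`overlap="keep"`,
exposure precedence — such co-suspect reports demonstrably exist), or
dropped with `overlap="exclude"`. The four cells are disjoint and sum to
the scope size, which the tests assert.

## Descriptive layer

Every summary table carries its denominator and the rule that defines it,
because case-series tables mix denominators: sex and age use reports with
the field documented, seriousness uses all cases, outcome uses reports with
a documented outcome (`unknown` counts as undocumented), drug withdrawal
uses reports where withdrawal status is recorded. Multi-select fields
(reporter qualification; suspected drugs) count once per report per
category and may legitimately sum past 100%. Percentages are
100·count/denominator rounded half-up to one decimal; quartiles use linear
interpolation between order statistics (numpy's default), a convention
fixed so interquartile ranges are exactly reproducible. Time to onset is
the earliest matching reaction onset minus the earliest start date among
query-matching drug entries, in whole days; partial year-month dates
resolve to the 15th and are flagged imputed, year-only dates are treated as
missing; negative intervals are returned flagged implausible but excluded
from medians by default, making the plausibility filter visible rather
than silent. Doses normalize to mg per 30-day month.

## Synthetic data

Real spontaneous-report databases are access-restricted, so validation
runs on synthetic stores.

**Simulator.** Each report draws suspected-drug indicators independently
from per-ingredient marginal probabilities and reaction indicators from
per-PT baselines; an association (drug set, PT, ρ) replaces the baseline
with min(1, ρ·baseline) whenever an associated drug is present. Reports
drawing zero drugs or zero reactions are redrawn so the store size is
exact. Demographics, country, reporter, seriousness, outcome, dates, dose
and per-field missingness follow configured laws; defaults emulate a
migraine-pharmacovigilance slice (drug marginals averaging about one drug
per report with common analgesics as background; event baselines of
0.3–12%; sex ratio 3:1 female; age normal(48, 16) clipped to 18–90; time
to onset log-normal with median 84 days and log-sd 2.25, matching a
reported median and IQR of 84 and 18–383 days; missingness 7% sex, 41%
age, 53% outcome, 35% dates, 55% dose). One global seeded numpy generator
drives all draws column-wise; identical seeds give byte-identical CSV
output (tested), which is the reproducibility property that matters here.

**Ground truth.** Because zero-drug reports are redrawn, the generated
population is conditioned on carrying at least one drug, which inflates
every drug marginal by 1/P(≥1 drug). The closed-form implied IC of an
injected association accounts for this:

    q  = (1 − Π_{d∈S}(1−p_d)) / (1 − Π_{all d}(1−p_d))
    IC_implied = log2( cond / (q·cond + (1−q)·base) ),  cond = min(1, ρ·base)

The analogous zero-reaction redraw is *not* corrected for; its effect on
the conditional-to-marginal ratio is second order at these marginals
(measured ≈ 0.01 bits at n = 50,000). `rho_for_implied_ic` inverts the
relation to find the multiplier realizing a target implied IC when no
clipping occurs.

**Fixtures.** `study_fixture()` is a deterministic 99-case series plus
background reports whose descriptive summaries realize a published count
pattern exactly (drug shares 56/28/13/1/1, 86 female of 93 documented, age
bands 29/27/2 of 58 with median 45 and IQR 35–57, 15 serious with 6
disabling, outcomes 31/3/13 of 47, withdrawal 23 of 68, times to onset
with median 84 and IQR 18–383, class-typical monthly doses, the published
co-reported-term ranking). `comparative_fixture()` is a count-faithful
skeleton store — one drug and one reaction per report — realizing the
comparative cell pattern 99/55,506 (class of interest), 43/47,417
(triptans), 142/129,222 (beta-blockers).

**What passing on synthetic data does not show.** Drugs are mutually
independent and non-associated events are independent of drugs — the null
structure the expected-count model assumes — so the simulator cannot
exhibit confounding by co-reporting, masking by competing signals,
duplicate reports, or reporting-rate dynamics over a drug's life cycle
(Weber-type effects, notoriety bias). Results on real data inherit all of
those threats; the package surfaces reject/missingness counts and explicit
denominators precisely because the synthetic benchmarks cannot stand in
for them.

## Validation problem sizes

The suite exercises: exact-count fixtures (99 cases; 232,429-report
comparative skeleton); signal recovery on 50,000 simulated reports with
one injected association calibrated to an implied IC of 3.3 (recovered
within 0.3 bits, ranked first among twelve screened pairs); ground-truth
convergence over n ∈ {2,000; 20,000; 200,000}; the null false-signal rate
over 400 replicates of 1,000 reports (observed well under the 7.5% bound;
the gamma interval is conservative at small counts); and brute-force
raw-CSV counting oracles on stores of up to 200 reports. These sizes keep
the full suite around half a minute on one CPU while leaving the
Monte-Carlo assertions comfortable margins.

## Known limitations

- The exact interval routine and shrinkage variant of production
  signal-detection pipelines vary; one-decimal agreement is the honest
  comparison level for published IC values, and a published value sitting
  at a rounding boundary (e.g. 0.45) can print either way.
- Whole-database ICs depend on margins that only the database operator can
  compute; the operations are provided but no desk-scale fixture can
  reproduce those numbers.
- No deduplication of suspected duplicate reports, no E2B XML ingestion,
  no WHODrug coding, no SMQ support; ROR/PRR/EBGM estimators are out of
  scope.
- `TermDictionary` models PT→HLT→SOC single-path only (no LLT/HLGT, no
  multi-axiality).
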