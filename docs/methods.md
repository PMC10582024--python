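# Methods

## Counting model

The unit of analysis is the individual case safety report (ICSR), never
the patient or the event mention. Every count in the package —
contingency cells, case counts, descriptive strata — is a deduplicated
report count: a report listing a drug twice, or two PTs from the same
SMQ, contributes once. Drug and PT labels are matched case-insensitively
after whitespace collapsing.

A report's drugs carry a role (suspect, concomitant, interacting). The
disproportionality layer filters the drug of interest to
suspect/interacting mentions by default, because causality-relevant
counting excludes purely concomitant mentions; descriptive tables use
all roles. Both are configurable per call.

## Contingency construction

For drug *x* and event set *S* (a single PT or an SMQ):

* A+B = reports where *x* appears with a role in the filter;
* the comparator universe is either every report (`all_drugs`) or every
  report mentioning at least one monoclonal antibody in any role
  (`all_mabs`; *x* itself must be flagged as a mAb);
* C+D = universe minus the role-filtered reports of *x* — so a report
  where *x* is concomitant-only sits on the comparator side, and the
  four cells always partition the universe;
* A (resp. C) are the reports in each group listing any PT in *S*.

An empty comparator side is fatal rather than producing degenerate
ratios.

## Statistics

PRR and ROR are computed exactly per their defining formulas with no
continuity correction. Zero cells make them undefined: the value is NaN,
carried through to a never-positive signal status. A Haldane-corrected
ROR (+0.5 on every cell) is computed alongside and exposed separately,
because silently correcting changes the estimand.

The information component uses the shrinkage observed/expected
estimator IC = log₂((O+½)/(E+½)) with E = (A+B)(A+C)/N. Two credibility
bounds are available:

* `approx` (default): IC₀₂₅ = IC − 3.3(O+½)^(−1/2) − 2.363(O+½)^(−3/4),
  the closed-form approximation in operational use with large
  spontaneous-report databases;
* `gamma_quantile`: log₂ of the 2.5% quantile of the
  Gamma(O+½, rate E+½) posterior of the observed-to-expected ratio.

The two agree closely at large counts (within 0.03 bits on the largest
published row, where the gamma variant reproduces the printed 3.17
exactly) and diverge at small counts, where the closed form is the more
conservative bound. Both satisfy IC₀₂₅ < IC on every table; the
shrinkage makes all-zero tables admissible (IC = 0).

The signal rule is conjunctive: A ≥ 3 and PRR ≥ 2 and ROR ≥ 2 and
IC₀₂₅ ≥ 0, all thresholds inclusive and configurable. The conjunctive
reading (rather than PRR/ROR only) is adopted because it reproduces
exactly the published positive/negative pattern across all 29
asthma-biologics rows, including the 4-report reslizumab row that
passes PRR/ROR but fails IC₀₂₅.

`ror_from_prr` back-solves the ROR implied by a printed
(count, drug total, PRR) triple: comparator proportion
p = (a/n)/PRR, comparator odds p/(1−p), drug odds a/(n−a). It exists so
printed result tables can be consistency-checked without database
access. At PRR = 1 the back-solved ROR is exactly 1; above 1 the odds
transform inflates it (ROR > PRR), below 1 it deflates — the same sign
concordance the real 2×2 formulas obey.

## Descriptive tables

Demographics are tabulated side by side for all reports and the SMQ
case reports. Every field has an explicit `unknown` stratum so
exhaustive blocks (sex, age band, reporter, region, year) sum to the
full denominator; drug and indication blocks are non-exclusive and
exempt. "Deaths" counts reports with a fatal outcome **or** a death
seriousness category, deduplicated — the union is the safest
report-level definition when the two granularities disagree.

The seriousness table scopes to each drug's *serious case* reports (any
role) and emits that denominator on every row, since published versions
of such tables rarely print theirs. The seriousness-category block is
multi-select (a case may be both hospitalized and life-threatening) and
may sum past its denominator; outcome, action-taken and
outcome-after-action blocks are single-select and sum exactly.

Display rounding is half-up: ratios at 2 decimals, percentages at 1 —
matching how safety tables are conventionally printed, and applied only
at the display/emission layer.

## Synthetic data generator

The generator emulates the structure of a large pharmacovigilance
database, not its full messiness. Per report: 1–3 drugs drawn from
catalog weights (duplicate draws merge, with transmitting roles taking
precedence over concomitant), a role per drug, demographics drawn
independently from categorical marginals, and each PT included with
probability

    background(pt) × max(ρ(drug, pt) over the report's
                         suspect/interacting drugs; 1 if none)

Signals are therefore planted multiplicatively on the per-report
inclusion probability, and because PRR is a ratio of report-level
proportions, the expected screened PRR of a planted pair equals ρ
when no other drug boosts the same PT. The approximation degrades as
background × ρ approaches 1, and ρ scaling past probability 1 is a
configuration error, reported with the offending pair. A report whose
event draw comes up empty receives a designated filler PT (never
case-defining), preserving the events-non-empty invariant without
touching report-level proportions.

Seriousness is drawn conditionally on case status (default 96.2% of
case reports serious vs 35% otherwise), then categories, outcome,
action and dechallenge outcome from their own marginals. The default
profile's demographic marginals follow the published all-report
distribution for the five asthma biologics (60.9% female, 31.9%
physician reporters, 80.8% Americas, …); its drug catalog gives the
five biologics half the slot mass in their published ratio plus 20
background drugs, and its signal matrix plants the published
anaphylaxis pattern (ρ = 9.61 for omalizumab down to a protective
0.39 for dupilumab).

Ground truth records, for every planted pair, the realized 2×2 cells
counted directly from the generation arrays — an independent path from
the analysis code, so generator and screen validate each other.

Randomness comes from a single seeded numpy `Generator` feeding
vectorized draws in a fixed order; identical seeds yield byte-identical
CSV output, which the pipeline tests verify end to end. (Per-report
counter-derived substreams were considered and rejected: there is no
parallel generation path, and a single stream keeps the draw budget
fixed and auditable.)

What the generator does **not** emulate — temporal reporting dynamics
(Weber effect), duplicate reports, masking/competition beyond what the
planted matrix induces, within-report demographic correlations, free-text
coding noise. Passing tests therefore demonstrate correctness of the
counting and statistics under clean sampling assumptions, not robustness
to real-world reporting artifacts.

## Problem sizes and numerical choices

The test and acceptance runs use synthetic databases of 800–3,000
reports for exact counting checks (where a brute-force per-report loop
is the oracle), 60,000 for the null false-positive run, 100,000 for
byte-level pipeline determinism, and 200,000 for parameter recovery at
ρ ∈ {2, 5, 10} — sized so each planted pair expects ≥ 50 case reports
and the Monte-Carlo standard error of log PRR (√(1/A − 1/(A+B) + 1/C −
1/(C+D))) gives a meaningful 3-SE recovery band.

Degenerate inputs are handled explicitly rather than numerically:
empty databases produce header-only outputs and zero percentages over
zero denominators; unknown drugs and malformed rows fail fast with the
offending name or line number.

## Known limitations

* Incidence cannot be estimated from spontaneous reports; nothing here
  attempts it.
* No multiplicity adjustment across screened pairs (none is standard in
  this design); the null-run false-positive rate quantifies the default
  rule's practical specificity instead.
* The miniature PT dictionary and bundled SMQ are working stand-ins for
  licensed MedDRA content; the SMQ file format accepts user-supplied
  licensed queries.
* Empirical-Bayes scorers (GPS/MGPS) and time-scan methods are out of
  scope.
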