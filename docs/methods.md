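# Methods

## Design of the case/non-case analysis

The package implements disproportionality analysis on spontaneous
adverse-event reports in the four-table layout used by JADER-style
databases (demographics, drugs, coded events, primary diseases, keyed by a
case id). The loader takes outer-join semantics — the report universe is
the union of case ids across tables, and missing fields stay missing — so
that the inclusion filters, not the parser, decide what enters the
analysis. The standard filters retain reports with non-missing sex, a
numeric decade age bucket (qualitative entries such as "elderly" count as
missing), and at least one recorded primary disease; an optional disease
set restricts the population (e.g. to diabetic patients). Age is only
available in decade bins (0–9 … 80–89, 90+), which is why the age
stratification threshold must sit on a decade boundary.

A report is a *case* when any of its event preferred terms (PTs) belongs to
the query PT set, and *exposed* when any suspect-role drug entry matches
the target drug or class. Both decisions are per report: multiple matching
drugs or PTs never increment a cell twice, so the four cells of the 2×2
table always partition the filtered database. Exposure counts suspect
drugs only by default — the convention of the field — with a
concomitant-inclusive mode behind a flag for sensitivity analyses. The
comparator is all other reports in the database; class-wide analyses do
not remove same-class drugs from the comparator. That choice is forced by
the arithmetic of marginal reconstruction: d = N − n₁₊ − c, which is what
makes published per-drug RORs (e.g. exenatide 11.08) recomputable from
printed marginals.

## Statistics

**ROR.** ad/bc with the Woolf (log-normal) interval
exp(ln ROR ± z·√(1/a+1/b+1/c+1/d)), z = 1.96. Undefined on any zero cell
(rendered as a dash, as published tables do for drugs without case
reports).

**PRR and χ².** PRR = (a/(a+b))/(c/(c+d)); χ² is the Pearson statistic of
the table (scipy), without Yates correction by default and with it behind
a flag — no published value pins the variant, and both are offered.

**IC.** The original BCPNN closed form. With C = N, c_x = n₁₊, c_y = n₊₁,
c_xy = a and priors (α₁, β₁, α, β, γ₁₁):

    γ     = γ₁₁ (C+α)(C+β) / ((c_x+α₁)(c_y+β₁))
    E(IC) = log₂[ (c_xy+γ₁₁)(C+α)(C+β) / ((C+γ)(c_x+α₁)(c_y+β₁)) ]
    V(IC) = ln2⁻² [ (C−c_xy+γ−γ₁₁)/((c_xy+γ₁₁)(1+C+γ))
                  + (C−c_x+α−α₁)/((c_x+α₁)(1+C+α))
                  + (C−c_y+β−β₁)/((c_y+β₁)(1+C+β)) ]

with credible bounds E(IC) ± 2√V(IC). The defaults α₁ = β₁ = γ₁₁ = 1,
α = β = 2 are the symmetric uniform-prior configuration; this exact
configuration (and not the later 0.5-shrinkage variant, nor 1.96-SD
bounds) reproduces the published incretin/GERD IC values to 2 decimal
places, which is the package's acceptance check for the implementation.
The IC is defined for every table, including zero cells, but is flagged
not-evaluable for signal purposes when a = 0.

**Criteria.** Signal: ROR lower 95% bound > 1, IC lower bound > 0
(each flag separate; "both" is their conjunction). Inverse signal: ROR
upper bound < 1 and IC upper bound < 0. Undefined statistics never raise
flags.

**Signal value.** sv = ln(PRR) + ln(χ²), defined only when both factors
are positive; stratum A dominates when sv_A > 2·sv_B strictly. The rule is
deliberately coarse — it compares a scalar mixing effect size and sample
size — and is provided as the published between-stratum comparison device,
not as a replacement for interval-based criteria. Stratified analyses
recompute the full signal inside each stratum as a standalone case/non-case
analysis with the stratum's own size as N.

**Rounding.** Display rounding is half-away-from-zero at 2 decimals and
happens only at serialization; all internal values keep full precision.
Comparisons against published values use the rounded display values.

## Time to onset

For each exposed report, time runs from the earliest suspect start date of
a target drug to the earliest onset date of a query-set event (cases,
event = true) or to the latest end date of target-drug use (non-cases,
censored). Times above 365 days are administratively censored at 365 —
including nominal cases whose onset falls beyond a year — and non-positive
date differences clamp to day 1, since the product-limit estimator needs
positive times and reporting databases record same-day onsets. Reports
lacking the required dates are excluded and tallied, mirroring how
published analyses report usable-record counts. All exposed reports enter
the curves (with the 365-day cap) rather than only those resolving within
a year; restricting to the first year happens through censoring, not
through record selection. Kaplan-Meier estimation and the two-group
log-rank test are delegated to lifelines; tests check them against a hand
product-limit computation and a label-permutation reference.

## The synthetic generator

`synthetic_data.simulate` draws, per report: sex, a decade age bucket,
primary diseases, suspect/concomitant drug exposures with start dates and
log-normal use durations, then events. Event probabilities start from
per-PT baselines and are multiplied by any applicable relative reporting
risk for exposed reports (optionally different above an age threshold),
capped at 1. Multipliers act on *reporting* probability, not biological
incidence: disproportionality estimates relative reporting, so the
injected multiplier is exactly the estimand, and tests can check recovery.
Drug-attributed events get onset dates at the attributing class's earliest
suspect start plus a Weibull latency; background events anchor at the
report's earliest exposure. Missingness (sex, age, dates, qualitative age
words) is applied last. Every report carries at least one event; when the
Bernoulli draws produce none, one event is drawn from the report's own
risk-adjusted probability vector, so conditioning on "something was
reported" preserves the injected relative risks.

The default configuration emulates the incretin/GERD study population:
38,887 reports, its sex split and decade age profile, per-drug exposure
probabilities equal to each drug's report share, GERD-PT baselines equal
to the study's unexposed event shares, injected class risks 5.6 (GLP-1
receptor agonists) and 0.54 (DPP-4 inhibitors), Weibull onset medians of
roughly 42 vs 104 days, and missingness rates of 5% (sex), 5% (age), 2%
(qualitative age) and 30% (each date field) — date missingness chosen to
match the study's reported fraction of reports lacking usable time-series
data. Two limitations are worth knowing: conditioning on at least one
event raises the composite GERD reporting share above the study's 1.7%
(to roughly 4–5%), and the generator models neither free-text drug-name
noise nor duplicate/notoriety reporting effects. Passing tests therefore
demonstrate correct recovery of injected reporting risks under an
idealized reporting process, not robustness to the biases of real
spontaneous data.

## Numerical and testing choices

* Exact reproduction: all 27 published ROR/IC rows (point estimates and
  bounds) are rebuilt from printed marginals and compared at 2 d.p.
* Independent oracles: brute-force row scans for filters and tables, an
  expected-counts χ² computation, a hand product-limit table, and a
  label-permutation log-rank reference keep the checks library-free where
  the implementation uses a library.
* Null calibration: the ROR signal criterion is exercised on 2,000 seeded
  null data sets (n = 10,000 reports each, exposed-case expectation ≈ 31);
  its firing rate is required to stay within [0.02, 0.09] around the
  nominal one-sided 2.5%. The replicate count is sized so Monte-Carlo
  noise (sd ≈ 0.004) cannot straddle the band edges.
* Multiplier recovery: mean estimated ROR within 15% of injected risks
  {1, 2, 5} at n = 50,000 reports (five seeds per multiplier).
* Simulation sizes throughout the suite (5,000–60,000 reports) are chosen
  to give the checked statistics stable operating characteristics at
  interactive runtimes.
* IC monotonicity in a is only guaranteed — and only tested — in the
  sparse-signal regime (a small against b, c and d): because the expected
  count (a+b)(a+c)/N itself grows with a, the IC can legitimately decrease
  in a outside that regime.
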