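# Methods

## The problem

Spontaneous adverse-event reporting systems such as FAERS collect suspected
drug–event reports without exposure denominators, so absolute risks cannot be
estimated. Disproportionality analysis instead asks whether a (drug, event)
pair is reported *more often than expected* given the drug's and the event's
overall reporting frequencies. For a target drug and an event (a MedDRA
preferred term, PT, or membership in a System Organ Class, SOC) the data
reduce to a 2×2 table over deduplicated reports:

|                    | event     | no event |
|--------------------|-----------|----------|
| target drug (PS)   | a         | b        |
| all other reports  | c         | d        |

with N = a+b+c+d. The counting unit is the deduplicated report: a report
contributes at most one count to any cell, and the comparator is every other
report in the dataset. Four statistics are computed per pair, and a pair is
a *signal* only when all four are simultaneously significant.

## Ingestion model

FAERS quarterly ASCII tables are `$`-delimited with a header row, Latin-1
encoded (legacy files are not valid UTF-8; undecodable bytes are replaced).
Dates are YYYYMMDD with partial forms YYYYMM/YYYY; missing components default
to the first month/day. Several versions of one case share a `caseid`; only
the most recent by FDA receipt date survives deduplication, with ties broken
by the larger report id (later-assigned key) and undated versions losing to
dated ones. "Report date" is taken to be the FDA receipt date (`fda_dt`);
the quarterly files also carry an initial-receipt date, and nothing in the
record model pins which one a given analysis used — this is a declared
convention, not an inference. Primary-suspect filtering matches target names
case-insensitively as substrings of both the verbatim drug name and the
active-ingredient field, so salt and brand suffixes ("TRAZODONE
HYDROCHLORIDE") still match. PTs are uppercased and deduplicated within a
report. Only PTs with at least `min_pt_count = 3` target reports are scored.

## The four statistics

**ROR** (reporting odds ratio): ad/(bc), with the lognormal Wald interval
exp(ln ROR ± z·√(1/a+1/b+1/c+1/d)), z = 1.96 at the default 95% level. When
any cell is zero the Haldane–Anscombe correction adds 0.5 to all four cells
and flags the result.

**PRR** (proportional reporting ratio): [a/(a+b)]/[c/(c+d)] with interval
exp(ln PRR ± z·√(1/a − 1/(a+b) + 1/c − 1/(c+d))), paired with the
Yates-corrected χ² on the 2×2 (summands max(|O−E|−½,0)²/E, so exact
independence scores 0). The uncorrected Pearson form is available by flag;
the corrected form is the spontaneous-reporting convention this package
follows.

**BCPNN information component**: IC = log₂ P(drug,event)/[P(drug)P(event)].
The classic closed-form posterior moments are used, with prior constants
α₁=β₁=1, α=β=2, γ₁₁=1 and the dependence parameter γ chosen so the prior IC
expectation is zero (formulas in `bayesian.py`). IC025 = E(IC) − 2√V(IC),
the classic two-standard-deviation bound (1.96 is *not* used here;
configurable).

*Accuracy limitation.* These moments are a large-count approximation. The
leading systematic error relative to the exact Dirichlet-posterior mean of
IC is roughly 0.72/a − 1.44/E bits, where E = (a+b)(a+c)/N is the expected
pair count: the −log₂(1+γ/N) term in the closed form behaves as −1.44/E.
For common events (a and E both ≳ 50, the regime of published signal-table
rows) the error is below ~0.03 bits and the closed form agrees with a
Monte-Carlo Dirichlet oracle to within 0.05; for a ≫ E with small E the
closed form shrinks much harder than the exact posterior (worked table
10/90/100/9800: closed form 2.375 vs exact 3.215). The verification suite
therefore samples tables with margins 5–15% of N = 20 000 and a ≥ 30; the
closed form should not be read as an exact posterior for rare events (its
2-SD bound is conservative there, which is the fail-safe direction for
screening).

**MGPS / EBGM** (DuMouchel gamma-Poisson shrinker): each cell's count n is
Poisson(λ·E) with a two-component gamma mixture prior on the relative
reporting rate λ:

    λ ~ w·Gamma(α₁, β₁) + (1−w)·Gamma(α₂, β₂)      (shape/rate)

Marginally n is a mixture of two negative binomials; the five
hyperparameters are estimated by maximum likelihood over all (suspect drug,
PT) cells of the dataset — cells with n ≥ 1 by default, DuMouchel's common
practice (toggle to include zeros; the recovery studies include them so the
MLE is unbiased for the generating truth). The optimizer is L-BFGS-B on the
unconstrained scale (log for positives, logit for w) from the customary
initialization (0.2, 0.1, 2, 4, ⅓) plus five seeded random restarts.
The search box is bounded to e^±12 per parameter: beyond that the
log-gamma differences in the likelihood cancel catastrophically and can
fabricate positive "log-likelihoods", which the optimizer would otherwise
chase (any candidate whose total log pmf is positive is rejected as a
numerical artifact). The returned prior never has lower likelihood than the
initialization.

The cell posterior is again a gamma mixture with component weight Q updated
by the likelihood ratio. EBGM is the geometric mean 2^{E[log₂ λ]} computed
via the digamma function; EBGM05 solves mixture-CDF(q) = 0.05 by Brent
root-finding bracketed between 0 and an expanded upper bound, to ~1e−12 on
the CDF. Stratified expected counts (age band × sex × reporting year,
Mantel–Haenszel form E = Σₛ (aₛ+bₛ)(aₛ+cₛ)/Nₛ) are available behind a flag;
year is included in the default stratification because reporting mixes
drift over a 20-year window.

## The conjunctive signal rule

Default thresholds, the standard quartet of the FAERS literature, all
overridable from a `key = value` config file:

| method | rule |
|--------|------|
| ROR    | lower 95% bound > 1 and a ≥ 3 |
| PRR    | PRR ≥ 2 and χ² ≥ 4 and a ≥ 3 |
| BCPNN  | IC025 > 0 |
| MGPS   | EBGM05 > 2 |

`is_signal` is the conjunction of the four. The rule is monotone in every
statistic and deliberately conservative; no multiplicity correction is
applied across PTs (none is conventional for this screening design).

## Report surfaces

Demographic breakdowns are printed per section with the section's own
denominator: report counts for year/gender/age/reporter/route, entry counts
for outcomes and indications (a report may contribute several entries), the
known-country total for the country section, and all reports (including the
unknown row) for time-to-onset. This is the only convention that reproduces
the published percentages from their counts (e.g. 1298 hospitalizations over
4949 outcome entries = 26.23%). Percentages round half-up to two decimals;
comparisons against published values are made at the printed precision.
Ages are normalized to years (months /12, days /365.25). Time to onset is
event date minus the earliest matched suspect-drug therapy start; negative
gaps and missing dates are "unknown". Onset bins: [0,7), [7,30), [30,180),
[180,360), ≥360 days. Age bands: <30, decade bands to 80, ≥80. SOC-level
rows use SOC-membership tables (a report counts once per SOC if any of its
PTs maps there), so SOC case counts exceed any single PT's. PT rows are
ranked by case count, ties broken by PT string.

## Synthetic data generator

The generator emulates the FAERS structure end to end: multi-version cases
(duplicate rate 10% by default, the earlier version backdated 30–400 days so
deduplication has real work to do), one PS drug per report plus
Poisson-many SS/C/I co-medications, Dirichlet-sampled drug and PT marginal
frequencies, per-report Bernoulli PT inclusion (mean 2.9 PTs per report, the
magnitude seen in real antidepressant cohorts), outcome codes, therapy
starts, indications, and demographic fields with missingness (31% missing
age, 8.5% missing sex, 22% missing country) matching a typical cohort. All
randomness derives from one seed through per-component sub-streams, so
adding one record type never perturbs another's draws.

Planted dependencies multiply the PT inclusion *odds* by λ when the drug is
the report's primary suspect — odds rather than probabilities so λ is
unbounded; for small base probabilities the two coincide. Optionally every
(drug, PT) pair receives a λ drawn from a two-component gamma mixture, the
MGPS generative model. The ground-truth object records planted λ's, the
analytic expected pair count n_PS·π′ given the realized PS assignment,
duplicate version ids and the exact post-dedup case count.

What the generator does *not* emulate: real FAERS marginal frequencies,
verbatim drug-name noise beyond salt suffixes, country-specific reporting
cultures, or secular trends. Passing tests therefore demonstrate the
correctness of the statistical machinery and the calibration of the
decision rule under a faithful structural model — not the reproduction of
any real drug's signal profile, which requires the multi-gigabyte FAERS
download.

## Verification design and problem sizes

* Published demographic percentages: all 80 printed rows recomputed exactly
  at printed precision from the section counts.
* Worked table (10, 90, 100, 9800): ROR, PRR, Yates χ², BCPNN IC against
  inline hand arithmetic to 4 significant figures.
* BCPNN: 50 common-event tables, closed form within 0.05 of 10⁵-draw
  Dirichlet-posterior Monte-Carlo moments (suite scope derived above).
* MGPS: EBGM05 verified as the 5th percentile by independent quadrature of
  the posterior density (≤ 1e−6); monotonicity in n; hyperparameter
  recovery within 10% (mixture-mean metric, invariant to component
  relabeling) on 5000 simulated cells.
* Null calibration: 500 replicates of 400 reports × 15 drugs × 30 PTs with
  no planted effects; flagged fraction of eligible pairs ≤ 5% (empirically
  ~0: the conjunctive rule is very conservative at this scale).
* Power: 100 replicates of 20 000 reports with one planted λ = 20 pair;
  detection ≥ 95% (empirically 100%).
* Pipeline: post-dedup counts equal generator ground truth exactly;
  re-running the analysis on the same inputs is byte-identical.

Replicate counts and per-replicate sizes were chosen as the smallest scales
at which the operating characteristics are stable across seeds.

## Known limitations

* No probabilistic record linkage beyond case-id deduplication, and no
  drug-name standardization dictionary; name matching is substring-based.
* The BCPNN closed form's small-count behavior (above).
* The MGPS fit excludes zero cells by default, which biases the fitted
  prior slightly upward relative to the full-likelihood fit; this is the
  field's common practice and is toggleable.
* The PT→SOC mapping is user-supplied (the real dictionary is licensed);
  multiaxial PTs are resolved by primary SOC only, with unmapped PTs routed
  to an `UNMAPPED` sentinel.
* Old-dialect (pre-2012, ISR-keyed) files are supported only to the extent
  that `isr` is accepted as the report-id column alias.
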