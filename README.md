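# faerspv

Disproportionality signal detection for FAERS spontaneous adverse-event
reports.

Post-marketing drug safety surveillance relies on spontaneous reporting
systems such as the FDA Adverse Event Reporting System (FAERS). These data
have no exposure denominators, so safety questions are asked in relative
terms: is the (drug, event) pair reported more often than the drug's and the
event's overall reporting frequencies would predict? `faerspv` implements
that workflow end to end for pharmacoepidemiologists and drug-safety teams:

* **Ingestion** of FAERS quarterly ASCII tables (DEMO, DRUG, REAC, OUTC,
  THER, INDI; `$`-delimited, Latin-1), case deduplication keeping the most
  recent report version, and primary-suspect filtering by drug name.
* **2×2 contingency tables** per drug–event pair over deduplicated reports,
  with optional age × sex × year stratification and PT→SOC rollup from a
  user-supplied MedDRA-style mapping.
* **Four disproportionality statistics** per pair: the reporting odds ratio
  (ROR) with 95% CI, the proportional reporting ratio (PRR) with 95% CI and
  Yates χ², the BCPNN information component IC with its IC025 lower bound,
  and the DuMouchel gamma-Poisson shrinker (MGPS) EBGM with EBGM05, fitted
  by empirical-Bayes maximum likelihood over all drug–event cells.
* **The conjunctive signal rule**: a pair is a signal only when all four
  methods pass their thresholds (ROR CI low > 1 & a ≥ 3; PRR ≥ 2 & χ² ≥ 4 &
  a ≥ 3; IC025 > 0; EBGM05 > 2 — all configurable).
* **Report tables**: demographic breakdowns with section percentages,
  time-to-onset bins, SOC-level signal intensities, top-PT rankings and
  per-PT age distributions.
* **A synthetic FAERS generator** with duplicate case versions, realistic
  missingness and planted drug–event dependencies of known strength, so the
  whole pipeline is testable offline with exact ground truth.

For a 2×2 table with a = target-drug reports with the event, b = without,
c / d the same for all other reports and N the total:

    ROR = ad/bc                PRR = [a/(a+b)] / [c/(c+d)]
    IC  = log2 P(drug,event)/[P(drug)P(event)]   (Bayesian posterior moments)
    EBGM = 2^{E[log2 λ]},  λ | n  under a two-component gamma-mixture prior
                                   fitted to all drug–event cells

Model details, numerical choices and known limitations are in
[docs/methods.md](docs/methods.md).

## Worked example

Generate a synthetic dataset of 2 000 cases with one planted signal
(inclusion-odds ratio λ = 20 for PT_0009 when the target drug is the
primary suspect), then run the full pipeline:

```bash
$ faerspv synth --out demo_data --n-reports 2000 --n-pts 40 --n-drugs 15 \
      --n-socs 6 --plant PT_0009:20 --seed 42
wrote 2210 DEMO rows (2000 cases) to demo_data

$ faerspv all --input demo_data --out demo_out --meddra demo_data/meddra.tsv \
      --drug trazodone --seed 42
reports_loaded        2210
cases_after_dedup     2000
target_reports        198
pts_observed          38
pts_eligible          35
signals               1
```

The 2 210 DEMO rows collapse to exactly 2 000 cases (210 duplicate versions
removed), 198 reports name the target drug as primary suspect, 35 PTs reach
the ≥ 3 report floor, and exactly one pair — the planted one — passes all
four methods. `demo_out/pt_signals.tsv` begins:

```
name     soc     case_reports  ror      ror_ci_low  ...  ic025    ebgm     ebgm05   is_signal
PT_0009  SOC_04  127           19.1418  13.705           1.78973  4.55457  4.51643  1
PT_0032  SOC_05  48            1.15856  0.821484         -0.331179 0.993779 0.968406 0
```

The planted pair is reported by 127 of the 198 target reports, with
ROR = 19.1 (95% CI 13.7–26.7), IC025 = 1.79 and EBGM05 = 4.52 — a signal by
every method — while unplanted PTs sit at ROR ≈ EBGM ≈ 1. The output
directory also contains `table1.tsv` (demographics with section
percentages), `soc_signals.tsv`, `signals_only.tsv` and a stage-count run
log. The same flow is available as a library via
`faerspv.run_pipeline(RunConfig(...))` or, piecewise, through
`read_faers_table` / `deduplicate_cases` / `filter_primary_suspect` /
`build_table` / `compute_ror` / `compute_prr` / `compute_bcpnn` /
`fit_mgps` / `mgps_posterior` / `decide_signal`.

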