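"""Verification studies: oracle comparisons and operating-characteristic
simulations for the four disproportionality methods.

Each function recomputes its quantity from scratch (no cached results) and
is deliberately paired with an independent route to the same number: hand
arithmetic for the worked table, Dirichlet Monte Carlo for the BCPNN closed
form, quadrature for the posterior percentile, simulation from known
hyperparameters for the MGPS fit, and generator ground truth for the
pipeline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import integrate, special

from . import faers_io
from .bayesian import (
    MgpsHyperparams,
    compute_bcpnn,
    fit_mgps,
    mgps_posterior,
    simulate_cells,
    _posterior_q,
)
from .contingency import ContingencyTable
from .frequentist import compute_prr, compute_ror
from .pipeline import analyze_cases
from .report_tables import breakdown, load_reference_demographics, round_half_up
from .synthetic import GeneratorConfig, generate

__all__ = [
    "WORKED_TABLE",
    "demographic_reference_rows",
    "worked_table_stats",
    "random_common_event_tables",
    "bcpnn_mc_comparison",
    "ebgm05_quadrature_error",
    "mgps_recovery",
    "null_calibration",
    "power_study",
    "dedup_and_determinism",
]

#: the worked 2x2 example used for all hand-arithmetic oracles
WORKED_TABLE = ContingencyTable(10, 90, 100, 9800)


# --------------------------------------------------------------------------
# published demographic percentages
# --------------------------------------------------------------------------

def demographic_reference_rows() -> list[tuple[str, str, float, float]]:
    """Recompute the published demographic percentages from their counts.

    Returns (section, label, computed_percent, published_percent) for every
    row whose percentage was published, where the computed value comes from
    the package's own section-percentage convention rounded at the published
    precision.
    """
    rows = load_reference_demographics()
    sections: dict[str, list[tuple[str, int, str | None]]] = {}
    for section, label, count, pct in rows:
        sections.setdefault(section, []).append((label, count, pct))
    out = []
    for section, entries in sections.items():
        counts = [(label, count) for label, count, _ in entries]
        result = breakdown(section, counts)
        for (label, count, printed), (_, _, computed) in zip(entries, result.rows):
            if printed is None:
                continue
            ndigits = len(printed.split(".")[1]) if "." in printed else 0
            out.append((section, label,
                        round_half_up(computed, ndigits), float(printed)))
    return out


# --------------------------------------------------------------------------
# closed-form oracles on the worked table
# --------------------------------------------------------------------------

def worked_table_stats() -> dict[str, float]:
    t = WORKED_TABLE
    ror = compute_ror(t)
    prr = compute_prr(t)
    bc = compute_bcpnn(t)
    return {
        "ror": ror.ror, "ror_ci_low": ror.ci_low, "ror_ci_high": ror.ci_high,
        "prr": prr.prr, "chisq": prr.chisq, "ic": bc.ic, "ic_sd": bc.ic_sd,
    }


# --------------------------------------------------------------------------
# BCPNN Monte-Carlo oracle
# --------------------------------------------------------------------------

def random_common_event_tables(
    rng: np.random.Generator, n_tables: int = 50, n_total: int = 20000,
    min_pair_count: int = 30,
) -> list[ContingencyTable]:
    """FAERS-like common-event tables: margins 5-15% of N, association
    ratio 0.7-1.5, sampled from the induced multinomial.

    The closed-form BCPNN moments carry a systematic error of roughly
    0.72/a - 1.44/E bits (a the observed and E the expected pair count), so
    they are only meaningful for common events.  The suite stays in that
    validity region: the margin ranges put the expected pair count at
    E >= 50 and ``min_pair_count`` floors the observed count (published
    PT-level signal rows run 50-610 reports).  See docs/methods.md."""
    tables = []
    while len(tables) < n_tables:
        p_row = rng.uniform(0.05, 0.15)
        p_col = rng.uniform(0.05, 0.15)
        ratio = rng.uniform(0.7, 1.5)
        p11 = ratio * p_row * p_col
        p = [p11, p_row - p11, p_col - p11, 1.0 - p_row - p_col + p11]
        counts = rng.multinomial(n_total, p)
        if counts.min() > 0 and counts[0] >= min_pair_count:
            tables.append(ContingencyTable(*map(int, counts)))
    return tables


def bcpnn_mc_comparison(
    seed: int, n_tables: int = 50, n_draws: int = 100_000
) -> dict[str, float]:
    """Closed-form IC moments vs. Monte-Carlo Dirichlet-posterior moments.

    For each table the oracle draws cell probabilities from the
    Dirichlet(1,1,1,1) posterior, forms IC = log2 p11/(p1. p.1) per draw and
    takes empirical mean and sd.  Returns the worst absolute deviations of
    the closed form across the suite.
    """
    rng = np.random.default_rng(seed)
    max_dic = 0.0
    max_dsd = 0.0
    for t in random_common_event_tables(rng, n_tables):
        res = compute_bcpnn(t)
        draws = rng.dirichlet([t.a + 1, t.b + 1, t.c + 1, t.d + 1], size=n_draws)
        ic = np.log2(draws[:, 0] / ((draws[:, 0] + draws[:, 1])
                                    * (draws[:, 0] + draws[:, 2])))
        max_dic = max(max_dic, abs(res.ic - float(ic.mean())))
        max_dsd = max(max_dsd, abs(res.ic_sd - float(ic.std(ddof=1))))
    return {"max_abs_ic_dev": max_dic, "max_abs_sd_dev": max_dsd,
            "n_tables": n_tables}


# --------------------------------------------------------------------------
# MGPS oracles
# --------------------------------------------------------------------------

def ebgm05_quadrature_error(
    h: MgpsHyperparams, cells: list[tuple[int, float]]
) -> float:
    """Max |posterior P(lambda <= EBGM05) - 0.05| by numerical integration
    of the posterior gamma-mixture density (independent of the CDF used by
    the root finder)."""
    worst = 0.0
    for n, e in cells:
        cell = mgps_posterior(n, e, h)
        q = _posterior_q(n, e, h)

        def pdf(x: float) -> float:
            l1 = ((h.alpha1 + n) * math.log(h.beta1 + e)
                  + (h.alpha1 + n - 1) * math.log(x) - (h.beta1 + e) * x
                  - special.gammaln(h.alpha1 + n))
            l2 = ((h.alpha2 + n) * math.log(h.beta2 + e)
                  + (h.alpha2 + n - 1) * math.log(x) - (h.beta2 + e) * x
                  - special.gammaln(h.alpha2 + n))
            return q * math.exp(l1) + (1 - q) * math.exp(l2)

        mass, _ = integrate.quad(pdf, 0.0, cell.ebgm05, limit=200)
        worst = max(worst, abs(mass - 0.05))
    return worst


@dataclass(frozen=True)
class RecoveryResult:
    true_mean: float
    fitted_mean: float

    @property
    def relative_error(self) -> float:
        return abs(self.fitted_mean - self.true_mean) / self.true_mean


def mgps_recovery(
    seed: int,
    n_cells: int = 5000,
    truth: MgpsHyperparams = MgpsHyperparams(1.5, 3.0, 3.0, 1.5, 0.4),
) -> RecoveryResult:
    """Simulate cells from known hyperparameters and refit.

    The comparison metric is the prior mixture mean E[lambda], which is
    invariant to component relabeling (the individual components of a
    mixture are not identifiable when the data do not separate them).
    """
    rng = np.random.default_rng(seed)
    cells = simulate_cells(truth, n_cells, rng)
    fitted = fit_mgps(cells, seed=seed)
    return RecoveryResult(true_mean=truth.mixture_mean,
                          fitted_mean=fitted.mixture_mean)


# --------------------------------------------------------------------------
# operating characteristics of the conjunctive rule
# --------------------------------------------------------------------------

NULL_CONFIG = dict(n_reports=400, n_drugs=15, n_pts=30, n_socs=6,
                   target_ps_rate=0.12, duplicate_case_rate=0.05)

POWER_CONFIG = dict(n_reports=20000, n_drugs=20, n_pts=50, n_socs=8,
                    target_ps_rate=0.05, duplicate_case_rate=0.05)

POWER_PT = "PT_0010"
POWER_LAMBDA = 20.0


def _cases_for(config: GeneratorConfig):
    ds = generate(config)
    demo = faers_io.deduplicate_cases(ds.demo)
    cases = faers_io.assemble_cases(demo, ds.drug, ds.reac, ds.outc,
                                    ds.ther, ds.indi)
    return ds, cases


def null_calibration(seed: int, n_reps: int = 500) -> dict[str, float]:
    """Empirical false-signal rate of the conjunctive rule with no planted
    dependencies: flagged eligible (target, PT) pairs over all replicates."""
    root = np.random.SeedSequence(seed)
    flagged = 0
    eligible = 0
    for child in root.spawn(n_reps):
        sub_seed = int(child.generate_state(1)[0] % (2**31))
        config = GeneratorConfig(seed=sub_seed, **NULL_CONFIG)
        _, cases = _cases_for(config)
        result = analyze_cases(cases, [config.target_drug_name],
                               mgps_restarts=2, seed=sub_seed)
        eligible += len(result.pt_results)
        flagged += sum(1 for r in result.pt_results if r.decision.is_signal)
    rate = flagged / eligible if eligible else 0.0
    return {"flagged": flagged, "eligible": eligible,
            "false_signal_pct": 100.0 * rate, "n_reps": n_reps}


def power_study(seed: int, n_reps: int = 100) -> dict[str, float]:
    """Detection rate for one planted pair with rate ratio 20 in 20,000
    synthetic reports."""
    root = np.random.SeedSequence(seed)
    hits = 0
    for child in root.spawn(n_reps):
        sub_seed = int(child.generate_state(1)[0] % (2**31))
        config = GeneratorConfig(
            seed=sub_seed,
            planted_signals=(("TRAZODONE", POWER_PT, POWER_LAMBDA),),
            **POWER_CONFIG,
        )
        _, cases = _cases_for(config)
        result = analyze_cases(cases, [config.target_drug_name],
                               pts=[POWER_PT], mgps_restarts=2, seed=sub_seed)
        if result.pt_results and result.pt_results[0].decision.is_signal:
            hits += 1
    return {"hits": hits, "n_reps": n_reps, "power_pct": 100.0 * hits / n_reps}


def dedup_and_determinism(seed: int) -> dict[str, float]:
    """Pipeline stage counts vs. generator ground truth, twice over.

    Returns the post-dedup case count, the generator's expectation, and a
    0/1 determinism flag (identical analysis both times from the same
    inputs)."""
    config = GeneratorConfig(n_reports=800, seed=seed,
                             planted_signals=(("TRAZODONE", "PT_0003", 8.0),))
    ds = generate(config)

    def run():
        demo = faers_io.deduplicate_cases(ds.demo)
        cases = faers_io.assemble_cases(demo, ds.drug, ds.reac, ds.outc,
                                        ds.ther, ds.indi)
        return analyze_cases(cases, [config.target_drug_name], seed=seed)

    r1, r2 = run(), run()
    same = (r1.stage_counts == r2.stage_counts
            and [x.to_row() for x in r1.pt_results]
            == [x.to_row() for x in r2.pt_results])
    return {
        "post_dedup_count": r1.stage_counts["reports_loaded"],
        "expected_post_dedup": ds.ground_truth.expected_post_dedup,
        "deterministic": 1.0 if same else 0.0,
    }
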