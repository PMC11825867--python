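"""Synthetic FAERS-format data with known structure.

The generator emulates the spontaneous-report data model: multi-version
cases sharing a case id, drug role codes, one-to-many report->PT reactions,
outcome codes, therapy start dates and demographic fields with realistic
missingness.  Drug and PT marginal frequencies are Dirichlet-sampled; a
report's PT set is Bernoulli per term, and for planted (drug, PT) pairs the
inclusion *odds* are multiplied by a rate ratio lambda when the drug is the
report's primary suspect (odds are used so lambda is unbounded).  Optionally
every (drug, PT) pair can receive a lambda drawn from a two-component gamma
mixture — the generative model the gamma-Poisson shrinker assumes.

Demographic mixes and missingness default to the values observed for a
typical antidepressant cohort in FAERS (53/39/8 female/male/unknown, ~31%
missing age, ~39% of reports without a usable onset interval); report dates
are uniform over 2004Q1-2024Q2.
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .bayesian import MgpsHyperparams
from .contingency import MeddraMap
from .records import (
    DemoRecord,
    DrugRecord,
    IndicationRecord,
    OutcomeRecord,
    ReacRecord,
    TherapyRecord,
)
from . import faers_io

__all__ = ["GeneratorConfig", "GroundTruth", "SyntheticDataset", "generate",
           "make_meddra_fixture"]

_WINDOW_START = dt.date(2004, 1, 1).toordinal()
_WINDOW_END = dt.date(2024, 6, 30).toordinal()

_OUTCOME_CODES = ("OT", "HO", "DE", "LT", "DS", "RI", "CA")
_OUTCOME_P = (0.39, 0.26, 0.228, 0.046, 0.039, 0.032, 0.005)
_REPORTER_CODES = ("CN", "MD", "PH", "OT", "LW", "RN")
_REPORTER_P = (0.40, 0.245, 0.222, 0.125, 0.0055, 0.0025)
_COUNTRIES = ("US", "GB", "CA", "ES", "JP", "DE", "FR", "IT")
_COUNTRY_P = (0.77, 0.05, 0.045, 0.015, 0.012, 0.01, 0.008, 0.09)
_ROUTES = ("ORAL", "OTHER", "TRANSPLACENTAL")
_ROUTE_P = (0.42, 0.57, 0.01)
_INDICATIONS = (
    "PRODUCT USED FOR UNKNOWN INDICATION", "INSOMNIA", "DEPRESSION",
    "SLEEP DISORDER", "ANXIETY", "SUICIDE ATTEMPT", "MAJOR DEPRESSION",
    "PAIN", "BIPOLAR DISORDER",
)
_INDICATION_P = (0.30, 0.22, 0.12, 0.11, 0.08, 0.05, 0.05, 0.04, 0.03)


@dataclass(frozen=True)
class GeneratorConfig:
    n_reports: int = 2000  # distinct cases (post-dedup count)
    n_drugs: int = 20  # background drugs beside the target
    n_pts: int = 50
    n_socs: int = 8
    target_drug_name: str = "TRAZODONE"
    target_ps_rate: float = 0.10  # fraction of reports with the target as PS
    planted_signals: tuple[tuple[str, str, float], ...] = ()
    background_lambda: MgpsHyperparams | None = None  # draw lambda for every pair
    duplicate_case_rate: float = 0.10
    mean_pts_per_report: float = 2.9
    mean_extra_drugs: float = 1.8
    missing_age: float = 0.31
    missing_sex: float = 0.085
    missing_country: float = 0.22
    missing_event_date: float = 0.30
    missing_start_date: float = 0.20
    missing_reporter: float = 0.064
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_reports, self.n_drugs, self.n_pts, self.n_socs) < 1:
            raise ValueError("n_reports, n_drugs, n_pts, n_socs must all be >= 1")
        for name in ("target_ps_rate", "duplicate_case_rate", "missing_age",
                     "missing_sex", "missing_country", "missing_event_date",
                     "missing_start_date", "missing_reporter"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be a probability, got {p}")
        for _, _, lam in self.planted_signals:
            if lam <= 0:
                raise ValueError("planted-signal rate multipliers must be positive")


@dataclass(frozen=True)
class GroundTruth:
    """What the generator actually planted, for oracle checks downstream."""

    pair_lambda: dict[tuple[str, str], float]
    expected_pair_counts: dict[tuple[str, str], float]  # E[a | PS assignment]
    duplicates: dict[str, list[str]]  # case_id -> its report-version ids
    expected_post_dedup: int
    n_target_ps: int

    def to_json(self) -> str:
        return json.dumps({
            "pair_lambda": {f"{d}|{p}": v for (d, p), v in self.pair_lambda.items()},
            "expected_pair_counts": {
                f"{d}|{p}": v for (d, p), v in self.expected_pair_counts.items()},
            "duplicates": self.duplicates,
            "expected_post_dedup": self.expected_post_dedup,
            "n_target_ps": self.n_target_ps,
        }, indent=1, sort_keys=True)


@dataclass
class SyntheticDataset:
    demo: list[DemoRecord]
    drug: list[DrugRecord]
    reac: list[ReacRecord]
    outc: list[OutcomeRecord]
    ther: list[TherapyRecord]
    indi: list[IndicationRecord]
    ground_truth: GroundTruth
    config: GeneratorConfig = field(repr=False, default=None)  # type: ignore[assignment]

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Emit the six FAERS ASCII files plus ground_truth.json."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {}
        for kind in faers_io.TABLE_KINDS:
            path = out / f"{kind}.txt"
            faers_io.write_faers_table(path, getattr(self, kind), kind)
            paths[kind] = path
        gt = out / "ground_truth.json"
        gt.write_text(self.ground_truth.to_json() + "\n")
        paths["ground_truth"] = gt
        return paths


def _drug_name(i: int) -> str:
    return f"DRUG_{i:03d}"


def _pt_name(j: int) -> str:
    return f"PT_{j + 1:04d}"


def generate(config: GeneratorConfig, out_dir: str | Path | None = None) -> SyntheticDataset:
    """Generate one synthetic dataset; optionally write it to ``out_dir``.

    All randomness flows from ``config.seed`` through per-component
    sub-streams, so e.g. adding outcome rows can never perturb the reaction
    draws of the same seed.
    """
    ss = np.random.SeedSequence(config.seed)
    streams = ss.spawn(7)
    rng_struct, rng_drug, rng_reac, rng_demo, rng_date, rng_child, rng_dup = (
        np.random.default_rng(s) for s in streams)

    n = config.n_reports
    n_drugs = config.n_drugs
    n_pts = config.n_pts
    drug_names = [config.target_drug_name.upper()] + [
        _drug_name(i + 1) for i in range(n_drugs)]
    pt_names = [_pt_name(j) for j in range(n_pts)]

    # --- marginal frequencies and the planted rate-ratio matrix -----------
    drug_w = rng_struct.dirichlet(np.full(n_drugs, 2.0))
    pt_w = rng_struct.dirichlet(np.full(n_pts, 2.0))
    pi_base = np.clip(config.mean_pts_per_report * pt_w, 1e-4, 0.5)

    lam = np.ones((n_drugs + 1, n_pts))
    if config.background_lambda is not None:
        h = config.background_lambda
        comp1 = rng_struct.random(lam.shape) < h.w
        lam = np.where(
            comp1,
            rng_struct.gamma(h.alpha1, 1.0 / h.beta1, size=lam.shape),
            rng_struct.gamma(h.alpha2, 1.0 / h.beta2, size=lam.shape),
        )
    drug_index = {name: i for i, name in enumerate(drug_names)}
    pt_index = {name: j for j, name in enumerate(pt_names)}
    for dname, pname, mult in config.planted_signals:
        di = drug_index[dname.upper()]
        pj = pt_index[pname.upper()]
        lam[di, pj] = mult

    # --- report-level structure ------------------------------------------
    case_ids = np.arange(1, n + 1)
    is_target = rng_drug.random(n) < config.target_ps_rate
    ps_idx = np.where(
        is_target, 0, 1 + rng_drug.choice(n_drugs, size=n, p=drug_w))

    odds = (pi_base / (1.0 - pi_base))[None, :] * lam[ps_idx]
    pi = odds / (1.0 + odds)
    reac_matrix = rng_reac.random((n, n_pts)) < pi

    n_extra = rng_drug.poisson(config.mean_extra_drugs, size=n)
    extra_roles = ("SS", "C", "I")

    # --- demographics ------------------------------------------------------
    sex = np.where(rng_demo.random(n) < 0.576, "F", "M")
    sex_missing = rng_demo.random(n) < config.missing_sex
    ages = np.clip(rng_demo.normal(56.0, 19.0, size=n), 1.0, 99.0).round(1)
    age_missing = rng_demo.random(n) < config.missing_age
    reporter = rng_demo.choice(_REPORTER_CODES, size=n, p=_REPORTER_P)
    reporter_missing = rng_demo.random(n) < config.missing_reporter
    country = rng_demo.choice(_COUNTRIES, size=n, p=_COUNTRY_P)
    country_missing = rng_demo.random(n) < config.missing_country
    route = rng_demo.choice(_ROUTES, size=n, p=_ROUTE_P)
    indication = rng_demo.choice(_INDICATIONS, size=n, p=_INDICATION_P)
    n_outc = np.minimum(rng_demo.poisson(0.95, size=n), 3)
    # units other than years exercise the normalization path
    unit_draw = rng_demo.random(n)

    # --- dates -------------------------------------------------------------
    report_ord = rng_date.integers(_WINDOW_START, _WINDOW_END + 1, size=n)
    event_gap = rng_date.integers(0, 300, size=n)
    event_missing = rng_date.random(n) < config.missing_event_date
    onset = np.floor(rng_date.exponential(60.0, size=n)).astype(int)
    onset_negative = rng_date.random(n) < 0.03  # therapy recorded after event
    start_missing = rng_date.random(n) < config.missing_start_date

    dup_mask = rng_dup.random(n) < config.duplicate_case_rate
    dup_backdate = rng_dup.integers(30, 400, size=n)

    demo: list[DemoRecord] = []
    drug: list[DrugRecord] = []
    reac: list[ReacRecord] = []
    outc: list[OutcomeRecord] = []
    ther: list[TherapyRecord] = []
    indi: list[IndicationRecord] = []
    duplicates: dict[str, list[str]] = {}

    pt_hits = [np.nonzero(reac_matrix[i])[0] for i in range(n)]

    for i in range(n):
        cid = str(case_ids[i])
        final_date = dt.date.fromordinal(int(report_ord[i]))
        if dup_mask[i]:
            # an earlier, superseded version precedes the surviving one
            versions = [
                (f"{case_ids[i] * 10 + 1}",
                 dt.date.fromordinal(int(report_ord[i] - dup_backdate[i]))),
                (f"{case_ids[i] * 10 + 2}", final_date),
            ]
            duplicates[cid] = [v[0] for v in versions]
        else:
            versions = [(f"{case_ids[i] * 10 + 1}", final_date)]

        event_date = (None if event_missing[i]
                      else dt.date.fromordinal(int(report_ord[i] - event_gap[i])))
        if start_missing[i] or event_date is None:
            start_date = None
        elif onset_negative[i]:
            start_date = event_date + dt.timedelta(days=int(onset[i]) + 1)
        else:
            start_date = event_date - dt.timedelta(days=int(onset[i]))

        age_val: float | None
        age_unit: str | None
        if age_missing[i]:
            age_val, age_unit = None, None
        elif unit_draw[i] < 0.02:
            age_val, age_unit = round(float(ages[i]) * 12.0, 1), "MON"
        else:
            age_val, age_unit = float(ages[i]), "YR"

        codes = list(dict.fromkeys(
            rng_child.choice(_OUTCOME_CODES, size=int(n_outc[i]), p=_OUTCOME_P)))
        extra_drug_ids = 1 + rng_child.choice(n_drugs, size=int(n_extra[i]), p=drug_w)
        extra_role_ids = rng_child.choice(3, size=int(n_extra[i]))

        for pid, rdate in versions:
            demo.append(DemoRecord(
                primary_id=pid,
                case_id=cid,
                report_date=rdate,
                age_value=age_val,
                age_unit=age_unit,
                sex=None if sex_missing[i] else str(sex[i]),
                reporter_type=None if reporter_missing[i] else str(reporter[i]),
                reporter_country=None if country_missing[i] else str(country[i]),
                event_date=event_date,
            ))
            name = drug_names[ps_idx[i]]
            drug.append(DrugRecord(pid, "1", "PS", name,
                                   active_ingredient=name, route=str(route[i])))
            for k, (di, ri) in enumerate(zip(extra_drug_ids, extra_role_ids)):
                drug.append(DrugRecord(pid, str(k + 2), extra_roles[ri],
                                       drug_names[di]))
            for j in pt_hits[i]:
                reac.append(ReacRecord(pid, pt_names[j]))
            for code in codes:
                outc.append(OutcomeRecord(pid, str(code)))
            ther.append(TherapyRecord(pid, "1", start_date))
            indi.append(IndicationRecord(pid, "1", str(indication[i])))

    # --- ground truth ------------------------------------------------------
    pair_lambda: dict[tuple[str, str], float] = {}
    expected: dict[tuple[str, str], float] = {}
    ps_counts = np.bincount(ps_idx, minlength=n_drugs + 1)
    for di, dname in enumerate(drug_names):
        for pj, pname in enumerate(pt_names):
            if lam[di, pj] != 1.0:
                pair_lambda[(dname, pname)] = float(lam[di, pj])
        # expectations recorded for planted pairs only (the pairs under study)
    for dname, pname, mult in config.planted_signals:
        di = drug_index[dname.upper()]
        pj = pt_index[pname.upper()]
        o = pi_base[pj] / (1.0 - pi_base[pj]) * lam[di, pj]
        expected[(dname.upper(), pname.upper())] = float(
            ps_counts[di] * o / (1.0 + o))

    truth = GroundTruth(
        pair_lambda=pair_lambda,
        expected_pair_counts=expected,
        duplicates=duplicates,
        expected_post_dedup=n,
        n_target_ps=int(ps_counts[0]),
    )
    ds = SyntheticDataset(demo=demo, drug=drug, reac=reac, outc=outc,
                          ther=ther, indi=indi, ground_truth=truth, config=config)
    if out_dir is not None:
        ds.write(out_dir)
    return ds


def make_meddra_fixture(
    n_pts: int, n_socs: int, seed: int, path: str | Path | None = None
) -> MeddraMap:
    """A deterministic, surjective PT -> SOC mapping for the generated terms.

    The PT order is permuted by the seed and SOCs assigned round-robin, so
    every SOC receives at least one PT whenever n_socs <= n_pts.
    """
    if n_socs > n_pts:
        raise ValueError("n_socs must not exceed n_pts")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_pts)
    mapping = {
        _pt_name(int(j)): f"SOC_{(k % n_socs) + 1:02d}"
        for k, j in enumerate(perm)
    }
    if path is not None:
        lines = ["pt\tsoc"] + [f"{pt}\t{soc}" for pt, soc in sorted(mapping.items())]
        Path(path).write_text("\n".join(lines) + "\n")
    return MeddraMap(mapping)
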