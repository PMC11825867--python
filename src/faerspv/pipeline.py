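"""End-to-end orchestration: ingest -> deduplicate -> primary-suspect filter
-> contingency tables -> four disproportionality statistics -> conjunctive
signal rule -> report tables."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from . import faers_io
from .bayesian import (
    DEFAULT_MGPS_INIT,
    MgpsHyperparams,
    compute_bcpnn,
    fit_mgps,
    mgps_posterior,
    stratified_expected,
)
from .contingency import (
    MeddraMap,
    build_stratified_tables,
    build_table,
    count_pt_occurrences,
    drug_event_cells,
    map_pt_to_soc,
)
from .frequentist import compute_prr, compute_ror
from .records import CaseReport
from .report_tables import (
    CategoryBreakdown,
    DisproResult,
    demographics_table,
    soc_table,
    top_pt_table,
    write_breakdowns_tsv,
    write_results_tsv,
)
from .signals import Thresholds, decide_signal

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "AnalysisResult", "analyze_cases", "load_quarter_dir",
           "run_pipeline"]


@dataclass
class RunConfig:
    input_dir: Path
    out_dir: Path
    drug_names: tuple[str, ...] = ("trazodone",)
    meddra_path: Path | None = None
    thresholds: Thresholds = field(default_factory=Thresholds)
    stratify: bool = False
    min_pt_count: int = 3
    seed: int = 0
    log_level: str = "INFO"


@dataclass
class AnalysisResult:
    stage_counts: dict[str, int]
    pt_results: list[DisproResult]
    soc_results: list[DisproResult]
    prior: MgpsHyperparams | None
    demographics: list[CategoryBreakdown]

    @property
    def signals(self) -> list[DisproResult]:
        return [r for r in self.pt_results if r.decision.is_signal]


def analyze_cases(
    cases: Sequence[CaseReport],
    target_names: Sequence[str],
    *,
    meddra: MeddraMap | None = None,
    thresholds: Thresholds = Thresholds(),
    stratify: bool = False,
    min_pt_count: int = 3,
    pts: Sequence[str] | None = None,
    mgps_restarts: int = 5,
    seed: int = 0,
) -> AnalysisResult:
    """Score drug-event pairs for a deduplicated case set.

    ``pts`` restricts scoring to the given preferred terms (the count filter
    still applies); by default every PT with at least ``min_pt_count``
    target-drug reports is scored.  The gamma-mixture prior is fitted once
    over all (suspect drug, PT) cells of the dataset, then applied to the
    target pairs.
    """
    target_cases = faers_io.filter_primary_suspect(cases, target_names)
    target_ids = {c.primary_id for c in target_cases}
    pt_counts = count_pt_occurrences(target_cases)
    eligible = sorted(pt for pt, cnt in pt_counts.items() if cnt >= min_pt_count)
    if pts is not None:
        wanted = {p.upper() for p in pts}
        eligible = [p for p in eligible if p in wanted]

    stage_counts = {
        "reports_loaded": len(cases),
        "target_reports": len(target_cases),
        "pts_observed": len(pt_counts),
        "pts_eligible": len(eligible),
    }

    prior: MgpsHyperparams | None = None
    if eligible or meddra is not None:
        cells = drug_event_cells(cases, stratify=stratify)
        if cells:
            prior = fit_mgps([(n, e) for _, _, n, e in cells],
                             DEFAULT_MGPS_INIT, n_restarts=mgps_restarts,
                             seed=seed)

    def score(name: str, event, soc: str | None) -> DisproResult:
        table = build_table(cases, target_ids, event)
        ror = compute_ror(table)
        prr = compute_prr(table)
        bc = compute_bcpnn(table)
        if stratify:
            e = stratified_expected(build_stratified_tables(cases, target_ids, event))
        else:
            e = table.expected_a
        cell = mgps_posterior(table.a, max(e, 1e-12), prior or DEFAULT_MGPS_INIT)
        decision = decide_signal(ror, prr, bc, cell, table.a, thresholds)
        return DisproResult(name=name, soc=soc, a=table.a, ror=ror, prr=prr,
                            bcpnn=bc, mgps=cell, decision=decision)

    pt_results = [
        score(pt, pt, meddra.soc_of(pt) if meddra else None) for pt in eligible
    ]

    soc_results: list[DisproResult] = []
    if meddra is not None:
        all_pts = {pt for c in target_cases for pt in c.pts}
        grouped = map_pt_to_soc(sorted(all_pts), meddra)
        soc_results = soc_table(
            score(soc, members, soc) for soc, members in grouped.items()
        )

    stage_counts["signals"] = sum(
        1 for r in pt_results if r.decision.is_signal)
    return AnalysisResult(
        stage_counts=stage_counts,
        pt_results=pt_results,
        soc_results=soc_results,
        prior=prior,
        demographics=demographics_table(target_cases),
    )


def load_quarter_dir(input_dir: str | Path) -> dict[str, list]:
    """Locate and read the six FAERS tables in a directory.

    File names are matched case-insensitively on the table prefix (demo,
    drug, reac, outc, ther, indi); a missing table is a hard error naming
    the file.
    """
    input_dir = Path(input_dir)
    tables: dict[str, list] = {}
    files = sorted(p for p in input_dir.iterdir() if p.is_file())
    for kind in faers_io.TABLE_KINDS:
        match = next(
            (p for p in files if p.name.lower().startswith(kind)), None)
        if match is None:
            raise FileNotFoundError(
                f"no {kind.upper()} table found in {input_dir} "
                f"(expected a file named like '{kind}*.txt')")
        tables[kind] = faers_io.read_faers_table(match, kind)
    return tables


def run_pipeline(config: RunConfig) -> AnalysisResult:
    """Run the full flow over a quarterly-format directory and write the
    report tables (table1.tsv, soc_signals.tsv, pt_signals.tsv,
    signals_only.tsv) plus a stage-count run log."""
    logging.basicConfig(level=config.log_level)
    tables = load_quarter_dir(config.input_dir)
    n_raw = len(tables["demo"])
    demo = faers_io.deduplicate_cases(tables["demo"])
    cases = faers_io.assemble_cases(
        demo, tables["drug"], tables["reac"], tables["outc"],
        tables["ther"], tables["indi"])
    meddra = MeddraMap.from_tsv(config.meddra_path) if config.meddra_path else None
    result = analyze_cases(
        cases,
        config.drug_names,
        meddra=meddra,
        thresholds=config.thresholds,
        stratify=config.stratify,
        min_pt_count=config.min_pt_count,
        seed=config.seed,
    )
    result.stage_counts = {
        "reports_loaded": n_raw,
        "cases_after_dedup": len(cases),
        **{k: v for k, v in result.stage_counts.items() if k != "reports_loaded"},
    }

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_breakdowns_tsv(out / "table1.tsv", result.demographics)
    write_results_tsv(out / "soc_signals.tsv", result.soc_results)
    write_results_tsv(out / "pt_signals.tsv", top_pt_table(
        result.pt_results, k=len(result.pt_results)))
    write_results_tsv(out / "signals_only.tsv", top_pt_table(
        result.signals, k=len(result.signals)))
    log_lines = [f"{key}\t{value}" for key, value in result.stage_counts.items()]
    (out / "run_log.txt").write_text("\n".join(log_lines) + "\n")
    for line in log_lines:
        logger.info("stage count: %s", line.replace("\t", " = "))
    return result
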