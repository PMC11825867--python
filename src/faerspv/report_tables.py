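"""Report surfaces: demographic breakdowns with section percentages,
time-to-onset binning, SOC-level and top-PT signal tables, and per-PT age
distributions.

Percentage conventions (chosen to match how spontaneous-report summaries are
printed): each section's denominator is the sum of its own rows — report
counts for gender/age/reporter/route/year, entry counts for outcomes and
indications (a report may contribute several), and the known-country total
for the country section.  Percentages are rounded half-up to two decimals.
"""

from __future__ import annotations

import datetime as dt
from collections import Counter, defaultdict
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

from .bayesian import BcpnnResult, MgpsCell
from .contingency import AGE_BAND_LABELS, MeddraMap, age_band
from .frequentist import PrrResult, RorResult
from .records import CaseReport
from .signals import SignalDecision

__all__ = [
    "CategoryBreakdown",
    "DisproResult",
    "round_half_up",
    "breakdown",
    "demographics_table",
    "time_to_onset",
    "onset_bin",
    "ONSET_BIN_LABELS",
    "soc_table",
    "top_pt_table",
    "age_distribution",
    "load_reference_demographics",
    "write_breakdowns_tsv",
    "write_results_tsv",
]

ONSET_BIN_LABELS = ("<7", "7~30", "30~180", "180~360", ">=360", "Unknown")

_OUTCOME_LABELS = {
    "OT": "Other serious",
    "HO": "Hospitalization",
    "DE": "Death",
    "LT": "Life threatening",
    "DS": "Disability",
    "RI": "Required intervention to Prevent Permanent Impairment/Damage",
    "CA": "Congenital anomaly",
}

_REPORTER_LABELS = {
    "CN": "Consumer",
    "MD": "Physician",
    "PH": "Pharmacist",
    "OT": "Other health-professional",
    "LW": "Lawyer",
    "RN": "Registered Nurse",
}

_SEX_LABELS = {"F": "Female", "M": "Male"}


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding (so 26.225 -> 26.23), as report tables print."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True, slots=True)
class CategoryBreakdown:
    section: str
    rows: tuple[tuple[str, int, float], ...]  # (label, count, percent)


def breakdown(
    section: str,
    counts: Sequence[tuple[str, int]],
    denominator: int | None = None,
) -> CategoryBreakdown:
    """Attach percentages to (label, count) rows.

    The denominator defaults to the section's own count sum; a caller may
    supply a larger one (e.g. when only the leading rows of a section are
    listed).
    """
    denom = denominator if denominator is not None else sum(c for _, c in counts)
    rows = tuple(
        (label, count, round_half_up(100.0 * count / denom) if denom else 0.0)
        for label, count in counts
    )
    return CategoryBreakdown(section=section, rows=rows)


def time_to_onset(case: CaseReport, matched_seqs: frozenset[str] | None = None) -> int | None:
    """Days from the earliest matched suspect-drug therapy start to the event.

    Missing dates or a negative gap (event before the therapy start) yield
    ``None`` ("unknown").
    """
    if matched_seqs is None:
        matched_seqs = case.matched_drug_seqs or frozenset(
            d.drug_seq for d in case.drugs if d.role == "PS")
    if case.demo.event_date is None:
        return None
    starts = [t.start_date for t in case.therapies
              if t.drug_seq in matched_seqs and t.start_date is not None]
    if not starts:
        return None
    days = (case.demo.event_date - min(starts)).days
    return days if days >= 0 else None


def onset_bin(days: int | None) -> str:
    if days is None:
        return "Unknown"
    for upper, label in ((7, "<7"), (30, "7~30"), (180, "30~180"), (360, "180~360")):
        if days < upper:
            return label
    return ">=360"


def _matched_route(case: CaseReport) -> str:
    seqs = case.matched_drug_seqs
    candidates = [d for d in case.drugs if (not seqs or d.drug_seq in seqs) and d.role == "PS"]
    for d in candidates:
        if d.route:
            return d.route.strip().title()
    return "Unknown"


def demographics_table(cases: Sequence[CaseReport], *, top_countries: int = 5) -> list[CategoryBreakdown]:
    """Per-section demographic breakdowns for the target-drug case set."""
    if not cases:
        return []
    years = Counter()
    sexes = Counter()
    ages = Counter()
    reporters = Counter()
    countries = Counter()
    routes = Counter()
    outcomes = Counter()
    onsets = Counter()
    indications = Counter()

    for case in cases:
        d = case.demo
        years[str(d.report_date.year) if d.report_date else "Unknown"] += 1
        sexes[_SEX_LABELS.get(d.sex or "", "Unknown")] += 1
        ages[age_band(case.age_years)] += 1
        reporters[_REPORTER_LABELS.get(d.reporter_type or "", "Unknown")] += 1
        if d.reporter_country:
            countries[d.reporter_country.strip()] += 1
        routes[_matched_route(case)] += 1
        for o in case.outcomes:
            outcomes[_OUTCOME_LABELS[o.outcome_code]] += 1
        onsets[onset_bin(time_to_onset(case))] += 1
        seqs = case.matched_drug_seqs
        for ind in case.indications:
            if not seqs or ind.drug_seq in seqs:
                indications[ind.indication_pt.strip().title()] += 1

    def ordered(counter: Counter, order: Iterable[str] | None = None):
        if order is not None:
            return [(label, counter[label]) for label in order if counter[label] > 0]
        return sorted(counter.items(), key=lambda kv: (-kv[1], kv[0]))

    sections = [
        breakdown("Year", sorted(years.items())),
        breakdown("Gender", ordered(sexes, ("Female", "Male", "Unknown"))),
        breakdown("Age", ordered(ages, AGE_BAND_LABELS)),
        breakdown("Reporter", ordered(reporters)),
    ]
    known_country_total = sum(countries.values())
    top = countries.most_common(top_countries)
    rest = known_country_total - sum(c for _, c in top)
    country_rows = top + ([("Other", rest)] if rest else [])
    sections.append(breakdown("Reported countries", country_rows,
                              denominator=known_country_total))
    sections.append(breakdown("Route", ordered(routes)))
    sections.append(breakdown("Outcomes", ordered(outcomes)))
    sections.append(breakdown("Time to event onset (days)",
                              ordered(onsets, ONSET_BIN_LABELS)))
    sections.append(breakdown("Indications", sorted(indications.items())))
    return sections


@dataclass(frozen=True, slots=True)
class DisproResult:
    """All four statistics for one drug-event pair — one signal-table row."""

    name: str  # PT, or SOC for SOC-level rows
    soc: str | None
    a: int
    ror: RorResult
    prr: PrrResult
    bcpnn: BcpnnResult
    mgps: MgpsCell
    decision: SignalDecision

    def to_row(self) -> dict[str, object]:
        return {
            "name": self.name,
            "soc": self.soc or "",
            "case_reports": self.a,
            "ror": self.ror.ror,
            "ror_ci_low": self.ror.ci_low,
            "ror_ci_high": self.ror.ci_high,
            "prr": self.prr.prr,
            "prr_ci_low": self.prr.ci_low,
            "prr_ci_high": self.prr.ci_high,
            "chisq": self.prr.chisq,
            "ic": self.bcpnn.ic,
            "ic025": self.bcpnn.ic025,
            "ebgm": self.mgps.ebgm,
            "ebgm05": self.mgps.ebgm05,
            "pass_ror": self.decision.pass_ror,
            "pass_prr": self.decision.pass_prr,
            "pass_bcpnn": self.decision.pass_bcpnn,
            "pass_mgps": self.decision.pass_mgps,
            "is_signal": self.decision.is_signal,
        }


def soc_table(soc_results: Iterable[DisproResult]) -> list[DisproResult]:
    """SOC rows sorted by case-report count descending (name breaks ties)."""
    return sorted(soc_results, key=lambda r: (-r.a, r.name))


def top_pt_table(pt_results: Iterable[DisproResult], k: int = 20) -> list[DisproResult]:
    """The k most-reported PTs; ties broken by PT string ascending."""
    ranked = sorted(pt_results, key=lambda r: (-r.a, r.name))
    return ranked[:k]


def age_distribution(
    cases: Sequence[CaseReport], pts: Iterable[str]
) -> tuple[dict[str, dict[str, int]], dict[str, int]]:
    """Per-PT histograms of reporter age bands among target cases.

    Returns (histograms, excluded) where ``excluded[pt]`` counts reports
    mentioning the PT whose age is unknown (not binned).
    """
    wanted = {pt.upper() for pt in pts}
    hist: dict[str, dict[str, int]] = {pt: defaultdict(int) for pt in wanted}
    excluded: dict[str, int] = {pt: 0 for pt in wanted}
    for case in cases:
        band = age_band(case.age_years)
        for pt in case.pts & wanted:
            if band == "Unknown":
                excluded[pt] += 1
            else:
                hist[pt][band] += 1
    return {pt: dict(h) for pt, h in hist.items()}, excluded


# --------------------------------------------------------------------------
# published reference counts & serialization
# --------------------------------------------------------------------------

def load_reference_demographics() -> list[tuple[str, str, int, str | None]]:
    """Published trazodone demographic section counts (FAERS 2004Q1-2024Q2).

    Returns (section, label, count, printed_percent) tuples; the printed
    percent is ``None`` for filler rows that only complete a section's
    denominator.
    """
    text = (resources.files("faerspv.data") / "trazodone_demographics.tsv").read_text()
    out = []
    for line in text.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        section, label, count, pct = line.split("\t")
        out.append((section, label, int(count), pct or None))
    return out


def write_breakdowns_tsv(path: str | Path, sections: Sequence[CategoryBreakdown]) -> None:
    lines = ["section\tlabel\tcount\tpercent"]
    for sec in sections:
        for label, count, pct in sec.rows:
            lines.append(f"{sec.section}\t{label}\t{count}\t{pct:.2f}")
    Path(path).write_text("\n".join(lines) + "\n")


_RESULT_COLUMNS = (
    "name", "soc", "case_reports", "ror", "ror_ci_low", "ror_ci_high",
    "prr", "prr_ci_low", "prr_ci_high", "chisq", "ic", "ic025",
    "ebgm", "ebgm05", "pass_ror", "pass_prr", "pass_bcpnn", "pass_mgps",
    "is_signal",
)


def write_results_tsv(path: str | Path, rows: Sequence[DisproResult]) -> None:
    def fmt(v: object) -> str:
        if isinstance(v, bool):
            return "1" if v else "0"
        if isinstance(v, float):
            return f"{v:.6g}"
        return str(v)

    lines = ["\t".join(_RESULT_COLUMNS)]
    for r in rows:
        row = r.to_row()
        lines.append("\t".join(fmt(row[c]) for c in _RESULT_COLUMNS))
    Path(path).write_text("\n".join(lines) + "\n")
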