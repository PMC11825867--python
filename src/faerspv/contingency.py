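"""2x2 contingency tables for drug-event pairs, stratification and SOC rollup.

The counting unit is the deduplicated report: a report contributes at most
one count to any cell.  For a target drug and an event (a PT, or membership
in a PT set such as an SOC) the table is

    a = target reports with the event       b = target reports without it
    c = other reports with the event        d = other reports without it

with N = a + b + c + d the total number of deduplicated reports.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .records import CaseReport

__all__ = [
    "ContingencyTable",
    "StratumKey",
    "MeddraMap",
    "AGE_BAND_LABELS",
    "age_band",
    "assign_stratum",
    "count_pt_occurrences",
    "build_table",
    "build_stratified_tables",
    "map_pt_to_soc",
    "drug_event_cells",
]

UNMAPPED_SOC = "UNMAPPED"

AGE_BAND_LABELS = ("<30", "30~40", "40~50", "50~60", "60~70", "70~80", ">=80", "Unknown")
_AGE_EDGES = (30.0, 40.0, 50.0, 60.0, 70.0, 80.0)


@dataclass(frozen=True, slots=True)
class ContingencyTable:
    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for cell in (self.a, self.b, self.c, self.d):
            if cell < 0 or cell != int(cell):
                raise ValueError("contingency cells must be nonnegative integers")

    @property
    def n_total(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def expected_a(self) -> float:
        """Expected count of cell a under row/column independence."""
        n = self.n_total
        if n == 0:
            return 0.0
        return (self.a + self.b) * (self.a + self.c) / n

    def __add__(self, other: "ContingencyTable") -> "ContingencyTable":
        return ContingencyTable(self.a + other.a, self.b + other.b,
                                self.c + other.c, self.d + other.d)


@dataclass(frozen=True, slots=True)
class StratumKey:
    """Age band x sex x reporting year; every report maps to exactly one."""

    age_band: str
    sex: str  # "F" / "M" / "Unknown"
    year: int  # 0 when the report date is missing


def age_band(age_years: float | None) -> str:
    if age_years is None or math.isnan(age_years):
        return "Unknown"
    for edge, label in zip(_AGE_EDGES, AGE_BAND_LABELS):
        if age_years < edge:
            return label
    return ">=80"


def assign_stratum(case: CaseReport) -> StratumKey:
    sex = case.demo.sex if case.demo.sex in ("F", "M") else "Unknown"
    year = case.demo.report_date.year if case.demo.report_date else 0
    return StratumKey(age_band(case.age_years), sex, year)


class MeddraMap:
    """Many-to-one PT -> primary SOC lookup (case-insensitive, total).

    Unmapped PTs resolve to the sentinel SOC ``"UNMAPPED"``.  The on-disk
    form is a two-column TSV ``pt<TAB>soc`` with an optional header line.
    """

    def __init__(self, mapping: Mapping[str, str]):
        self._map = {pt.strip().upper(): soc.strip() for pt, soc in mapping.items()}

    @classmethod
    def from_tsv(cls, path: str | Path) -> "MeddraMap":
        mapping: dict[str, str] = {}
        with open(path, "r", encoding="utf-8") as fh:
            for i, line in enumerate(fh):
                line = line.rstrip("\n")
                if not line.strip() or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) < 2:
                    raise ValueError(f"{path}:{i + 1}: expected 'pt<TAB>soc'")
                pt, soc = parts[0], parts[1]
                if i == 0 and pt.strip().lower() == "pt" and soc.strip().lower() == "soc":
                    continue  # header line
                mapping[pt] = soc
        return cls(mapping)

    def soc_of(self, pt: str) -> str:
        return self._map.get(pt.strip().upper(), UNMAPPED_SOC)

    def socs(self) -> list[str]:
        return sorted(set(self._map.values()))

    def __len__(self) -> int:
        return len(self._map)


def count_pt_occurrences(cases: Sequence[CaseReport]) -> dict[str, int]:
    """Number of distinct reports mentioning each PT (not PT rows)."""
    counts: dict[str, int] = defaultdict(int)
    for case in cases:
        for pt in case.pts:
            counts[pt] += 1
    return dict(counts)


def _event_reports(cases: Sequence[CaseReport], event_pts: frozenset[str]) -> set[str]:
    return {c.primary_id for c in cases if c.pts & event_pts}


def build_table(
    cases: Sequence[CaseReport],
    target_ids: set[str] | frozenset[str],
    pt: str | Iterable[str],
) -> ContingencyTable:
    """Build the 2x2 table for one event against the whole dataset.

    ``target_ids`` holds the report ids flagged by the primary-suspect
    filter; ``pt`` may be a single preferred term or an iterable of PTs (the
    event is then membership in the set, used for SOC-level tables).
    """
    event = frozenset([pt.upper()]) if isinstance(pt, str) else frozenset(
        p.upper() for p in pt)
    n = len(cases)
    n_target = sum(1 for c in cases if c.primary_id in target_ids)
    with_event = _event_reports(cases, event)
    a = sum(1 for pid in with_event if pid in target_ids)
    c = len(with_event) - a
    return ContingencyTable(a, n_target - a, c, n - n_target - c)


def build_stratified_tables(
    cases: Sequence[CaseReport],
    target_ids: set[str] | frozenset[str],
    pt: str | Iterable[str],
) -> dict[StratumKey, ContingencyTable]:
    """Per-stratum tables; cellwise sums reproduce the pooled table."""
    groups: dict[StratumKey, list[CaseReport]] = defaultdict(list)
    for case in cases:
        groups[assign_stratum(case)].append(case)
    return {key: build_table(members, target_ids, pt)
            for key, members in groups.items()}


def map_pt_to_soc(pts: Iterable[str], mm: MeddraMap) -> dict[str, list[str]]:
    """Group PTs by their primary SOC (unmapped PTs under ``"UNMAPPED"``)."""
    grouped: dict[str, list[str]] = defaultdict(list)
    for pt in pts:
        grouped[mm.soc_of(pt)].append(pt)
    return {soc: sorted(members) for soc, members in grouped.items()}


def drug_event_cells(
    cases: Sequence[CaseReport],
    *,
    stratify: bool = False,
    include_zero: bool = False,
) -> list[tuple[str, str, int, float]]:
    """Observed/expected count pairs over all (suspect drug, PT) cells.

    For each uppercased primary-suspect drug name D and each PT observed in
    the dataset, n is the number of reports carrying both and e the expected
    count under independence, e = n_D * n_PT / N, optionally summed within
    age x sex x year strata.  Cells with n = 0 are excluded unless
    ``include_zero`` (the prior-fitting convention for gamma-Poisson
    shrinkage, which fits observed cells only).

    Returns tuples (drug, pt, n, e) sorted by (drug, pt).
    """
    def cells_for(subset: Sequence[CaseReport]) -> dict[tuple[str, str], tuple[int, float]]:
        n_reports = len(subset)
        if n_reports == 0:
            return {}
        drug_reports: dict[str, set[str]] = defaultdict(set)
        pt_reports: dict[str, set[str]] = defaultdict(set)
        for case in subset:
            for d in case.drugs:
                if d.role == "PS" and d.drug_name:
                    drug_reports[d.drug_name.strip().upper()].add(case.primary_id)
            for pt in case.pts:
                pt_reports[pt].add(case.primary_id)
        out: dict[tuple[str, str], tuple[int, float]] = {}
        for drug, dr in drug_reports.items():
            for pt, pr in pt_reports.items():
                n = len(dr & pr)
                e = len(dr) * len(pr) / n_reports
                out[(drug, pt)] = (n, e)
        return out

    if not stratify:
        merged = cells_for(cases)
    else:
        groups: dict[StratumKey, list[CaseReport]] = defaultdict(list)
        for case in cases:
            groups[assign_stratum(case)].append(case)
        merged = {}
        for members in groups.values():
            for key, (n, e) in cells_for(members).items():
                n0, e0 = merged.get(key, (0, 0.0))
                merged[key] = (n0 + n, e0 + e)
    return sorted(
        (drug, pt, n, e)
        for (drug, pt), (n, e) in merged.items()
        if (n > 0 or include_zero) and e > 0
    )
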