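"""Reading, writing and case assembly for FAERS quarterly ASCII tables.

The public FAERS dialect is a header line plus one ``$``-delimited record per
line, Latin-1 encoded, with empty fields meaning "missing".  Dates appear as
YYYYMMDD with partial forms YYYYMM / YYYY (missing components default to the
first month/day).
"""

from __future__ import annotations

import datetime as dt
import logging
from collections import defaultdict
from pathlib import Path
from typing import Iterable, Sequence

from .records import (
    CaseReport,
    DemoRecord,
    DrugRecord,
    IndicationRecord,
    OutcomeRecord,
    ReacRecord,
    TherapyRecord,
)

logger = logging.getLogger(__name__)

__all__ = [
    "read_faers_table",
    "write_faers_table",
    "parse_faers_date",
    "format_faers_date",
    "deduplicate_cases",
    "assemble_cases",
    "filter_primary_suspect",
    "TABLE_KINDS",
]

TABLE_KINDS = ("demo", "drug", "reac", "outc", "ther", "indi")

# canonical field -> accepted header aliases (matched case-insensitively).
# `isr` is the pre-2012 report key, accepted as a primary_id alias.
_FIELD_ALIASES: dict[str, dict[str, tuple[str, ...]]] = {
    "demo": {
        "primary_id": ("primaryid", "isr"),
        "case_id": ("caseid", "case"),
        "report_date": ("fda_dt",),
        "event_date": ("event_dt",),
        "age_value": ("age",),
        "age_unit": ("age_cod",),
        "sex": ("sex", "gndr_cod"),
        "reporter_type": ("occp_cod",),
        "reporter_country": ("occr_country", "reporter_country"),
    },
    "drug": {
        "primary_id": ("primaryid", "isr"),
        "drug_seq": ("drug_seq",),
        "role": ("role_cod",),
        "drug_name": ("drugname",),
        "active_ingredient": ("prod_ai",),
        "route": ("route",),
    },
    "reac": {
        "primary_id": ("primaryid", "isr"),
        "pt": ("pt",),
    },
    "outc": {
        "primary_id": ("primaryid", "isr"),
        "outcome_code": ("outc_cod", "outc_code"),
    },
    "ther": {
        "primary_id": ("primaryid", "isr"),
        "drug_seq": ("dsg_drug_seq", "drug_seq"),
        "start_date": ("start_dt",),
    },
    "indi": {
        "primary_id": ("primaryid", "isr"),
        "drug_seq": ("indi_drug_seq", "drug_seq"),
        "indication_pt": ("indi_pt",),
    },
}

# canonical output headers used by write_faers_table
_WRITE_HEADERS: dict[str, tuple[tuple[str, str], ...]] = {
    "demo": (
        ("primaryid", "primary_id"),
        ("caseid", "case_id"),
        ("fda_dt", "report_date"),
        ("event_dt", "event_date"),
        ("age", "age_value"),
        ("age_cod", "age_unit"),
        ("sex", "sex"),
        ("occp_cod", "reporter_type"),
        ("occr_country", "reporter_country"),
    ),
    "drug": (
        ("primaryid", "primary_id"),
        ("drug_seq", "drug_seq"),
        ("role_cod", "role"),
        ("drugname", "drug_name"),
        ("prod_ai", "active_ingredient"),
        ("route", "route"),
    ),
    "reac": (("primaryid", "primary_id"), ("pt", "pt")),
    "outc": (("primaryid", "primary_id"), ("outc_cod", "outcome_code")),
    "ther": (
        ("primaryid", "primary_id"),
        ("dsg_drug_seq", "drug_seq"),
        ("start_dt", "start_date"),
    ),
    "indi": (
        ("primaryid", "primary_id"),
        ("indi_drug_seq", "drug_seq"),
        ("indi_pt", "indication_pt"),
    ),
}

_RECORD_TYPES = {
    "demo": DemoRecord,
    "drug": DrugRecord,
    "reac": ReacRecord,
    "outc": OutcomeRecord,
    "ther": TherapyRecord,
    "indi": IndicationRecord,
}

_DATE_FIELDS = {"report_date", "event_date", "start_date"}


def parse_faers_date(text: str | None) -> dt.date | None:
    """Parse YYYYMMDD / YYYYMM / YYYY; missing parts default to 01.

    Returns ``None`` for empty input; raises ``ValueError`` for garbage.
    """
    if text is None:
        return None
    text = text.strip()
    if not text:
        return None
    if not text.isdigit() or len(text) not in (4, 6, 8):
        raise ValueError(f"unparseable FAERS date {text!r}")
    year = int(text[:4])
    month = int(text[4:6]) if len(text) >= 6 else 1
    day = int(text[6:8]) if len(text) == 8 else 1
    return dt.date(year, month, day)


def format_faers_date(d: dt.date | None) -> str:
    return "" if d is None else d.strftime("%Y%m%d")


def _split_line(line: str) -> list[str]:
    return line.rstrip("\r\n").split("$")


def read_faers_table(path: str | Path, table_kind: str) -> list:
    """Read one FAERS ASCII table into a list of record objects.

    Empty fields become ``None``; extra unknown columns are ignored; header
    names are matched case-insensitively against the known aliases.  A row
    with an unparseable date keeps the record but drops the date (counted in
    a single warning per file).  A missing ``primaryid`` column is a hard
    error.
    """
    kind = table_kind.lower()
    if kind not in _FIELD_ALIASES:
        raise ValueError(f"unknown table kind {table_kind!r}")
    path = Path(path)
    with open(path, "r", encoding="latin-1", errors="replace") as fh:
        lines = fh.read().splitlines()
    if not lines:
        return []
    header = [h.strip().lower() for h in _split_line(lines[0])]
    col_of: dict[str, int] = {}
    for field_name, aliases in _FIELD_ALIASES[kind].items():
        for alias in aliases:
            if alias in header:
                col_of[field_name] = header.index(alias)
                break
    if "primary_id" not in col_of:
        raise ValueError(
            f"{path}: missing mandatory column 'primaryid' (or 'isr') "
            f"in {kind.upper()} header"
        )
    return _rows_to_records(
        ( _split_line(ln) for ln in lines[1:] if ln.strip() ),
        kind,
        col_of,
        source=str(path),
    )


def _rows_to_records(rows: Iterable[Sequence[str]], kind: str, col_of: dict[str, int],
                     source: str = "<memory>") -> list:
    rec_type = _RECORD_TYPES[kind]
    out = []
    bad_dates = 0
    for fields in rows:
        kwargs: dict[str, object] = {}
        for name, idx in col_of.items():
            raw = fields[idx].strip() if idx < len(fields) else ""
            if raw == "":
                kwargs[name] = None
                continue
            if name in _DATE_FIELDS:
                try:
                    kwargs[name] = parse_faers_date(raw)
                except ValueError:
                    kwargs[name] = None
                    bad_dates += 1
            elif name == "age_value":
                try:
                    kwargs[name] = float(raw)
                except ValueError:
                    kwargs[name] = None
            elif name in ("sex", "role", "outcome_code", "age_unit", "reporter_type"):
                kwargs[name] = raw.upper()
            else:
                kwargs[name] = raw
        # mandatory non-null string fields fall back to empty-string sentinels
        for required in ("primary_id", "case_id", "drug_seq", "drug_name",
                         "pt", "indication_pt", "role", "outcome_code"):
            if required in col_of and kwargs.get(required) is None:
                kwargs[required] = ""
        if kwargs.get("primary_id") in (None, ""):
            continue  # unkeyed row is unusable
        try:
            out.append(rec_type(**kwargs))
        except ValueError:
            continue  # invalid enum code; row dropped
    if bad_dates:
        logger.warning("%s: %d unparseable date value(s) treated as missing",
                       source, bad_dates)
    return out


def write_faers_table(path: str | Path, records: Iterable, table_kind: str) -> None:
    """Write records back to the ``$``-delimited FAERS dialect."""
    kind = table_kind.lower()
    layout = _WRITE_HEADERS[kind]
    lines = ["$".join(h for h, _ in layout)]
    for rec in records:
        fields = []
        for _, attr in layout:
            val = getattr(rec, attr)
            if val is None:
                fields.append("")
            elif attr in _DATE_FIELDS:
                fields.append(format_faers_date(val))
            elif attr == "age_value":
                fields.append(f"{val:g}")
            else:
                fields.append(str(val))
        lines.append("$".join(fields))
    Path(path).write_text("\n".join(lines) + "\n", encoding="latin-1")


def _pid_key(pid: str) -> tuple:
    """Sort key for report ids: numeric when possible, else lexicographic."""
    try:
        return (0, int(pid), "")
    except (TypeError, ValueError):
        return (1, 0, pid or "")


def _dedup_key(rec: DemoRecord) -> tuple:
    date = rec.report_date or dt.date.min  # undated reports lose ties
    return (date, _pid_key(rec.primary_id))


def deduplicate_cases(demo: list[DemoRecord]) -> list[DemoRecord]:
    """Keep one report per case: the most recent by report date.

    Ties on report date are broken by the larger report id (the later-assigned
    key); a report with no date sorts before any dated report.  Output order
    follows first appearance of each case.
    """
    best: dict[str, DemoRecord] = {}
    order: list[str] = []
    for rec in demo:
        cid = rec.case_id
        if cid not in best:
            best[cid] = rec
            order.append(cid)
        elif _dedup_key(rec) > _dedup_key(best[cid]):
            best[cid] = rec
    return [best[cid] for cid in order]


def assemble_cases(
    demo: list[DemoRecord],
    drug: list[DrugRecord] = (),
    reac: list[ReacRecord] = (),
    outc: list[OutcomeRecord] = (),
    ther: list[TherapyRecord] = (),
    indi: list[IndicationRecord] = (),
) -> list[CaseReport]:
    """Join child tables onto deduplicated DEMO rows by report id.

    Child rows referencing a report id absent from ``demo`` are dropped (one
    logged count per table).  Reaction PTs are uppercased and deduplicated
    within each report.
    """
    by_pid = {rec.primary_id: CaseReport(demo=rec) for rec in demo}
    dropped: dict[str, int] = defaultdict(int)

    for d in drug:
        case = by_pid.get(d.primary_id)
        if case is None:
            dropped["drug"] += 1
        else:
            case.drugs.append(d)
    seen_pts: dict[str, set[str]] = defaultdict(set)
    for r in reac:
        case = by_pid.get(r.primary_id)
        if case is None:
            dropped["reac"] += 1
            continue
        pt = r.pt.strip().upper()
        if pt and pt not in seen_pts[r.primary_id]:
            seen_pts[r.primary_id].add(pt)
            case.reactions.append(ReacRecord(r.primary_id, pt))
    for o in outc:
        case = by_pid.get(o.primary_id)
        if case is None:
            dropped["outc"] += 1
        else:
            case.outcomes.append(o)
    for t in ther:
        case = by_pid.get(t.primary_id)
        if case is None:
            dropped["ther"] += 1
        else:
            case.therapies.append(t)
    for i in indi:
        case = by_pid.get(i.primary_id)
        if case is None:
            dropped["indi"] += 1
        else:
            case.indications.append(i)
    for table, count in sorted(dropped.items()):
        logger.info("assemble_cases: dropped %d orphan %s row(s)", count, table.upper())
    return list(by_pid.values())


def filter_primary_suspect(
    cases: list[CaseReport], drug_names: Sequence[str]
) -> list[CaseReport]:
    """Keep cases where a primary-suspect drug matches a target name.

    Matching is case-insensitive substring against both the verbatim drug
    name and the active ingredient, so salt and brand suffixes still match.
    Returned cases carry the matching ``drug_seq`` set.
    """
    targets = [name.strip().lower() for name in drug_names if name.strip()]
    if not targets:
        raise ValueError("drug_names must contain at least one non-empty name")
    kept: list[CaseReport] = []
    for case in cases:
        seqs = set()
        for d in case.drugs:
            if d.role != "PS":
                continue
            haystacks = (d.drug_name or "", d.active_ingredient or "")
            if any(t in h.lower() for t in targets for h in haystacks):
                seqs.add(d.drug_seq)
        if seqs:
            kept.append(case.with_matches(frozenset(seqs)))
    return kept
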