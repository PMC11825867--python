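"""Case-level data model for spontaneous adverse-event reports.

A FAERS quarterly release splits each report across six tables keyed by a
report identifier (``primaryid``): demographics (DEMO), drugs with role codes
(DRUG), MedDRA-coded reactions (REAC), seriousness outcomes (OUTC), therapy
dates (THER) and treatment indications (INDI).  Several versions of the same
case may coexist (shared ``caseid``); only one survives deduplication.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace

__all__ = [
    "DemoRecord",
    "DrugRecord",
    "ReacRecord",
    "OutcomeRecord",
    "TherapyRecord",
    "IndicationRecord",
    "CaseReport",
    "age_in_years",
]

#: FAERS drug role codes: primary suspect, secondary suspect, concomitant,
#: interacting.
DRUG_ROLES = frozenset({"PS", "SS", "C", "I"})

#: FAERS seriousness outcome codes: death, life-threatening, hospitalization,
#: disability, congenital anomaly, required intervention, other serious.
OUTCOME_CODES = frozenset({"DE", "LT", "HO", "DS", "CA", "RI", "OT"})


@dataclass(slots=True)
class DemoRecord:
    """One row of the DEMO table: demographics for one report version."""

    primary_id: str
    case_id: str
    report_date: dt.date | None = None  # FDA receipt date (fda_dt)
    age_value: float | None = None
    age_unit: str | None = None  # YR / MON / DY
    sex: str | None = None  # F / M, None when unknown
    reporter_type: str | None = None  # CN / MD / PH / OT / LW / RN
    reporter_country: str | None = None
    event_date: dt.date | None = None


@dataclass(slots=True)
class DrugRecord:
    """One row of the DRUG table: a drug mention with its role code."""

    primary_id: str
    drug_seq: str
    role: str  # PS / SS / C / I
    drug_name: str
    active_ingredient: str | None = None
    route: str | None = None

    def __post_init__(self) -> None:
        if self.role not in DRUG_ROLES:
            raise ValueError(f"invalid drug role code {self.role!r}")


@dataclass(slots=True)
class ReacRecord:
    """One row of the REAC table: a MedDRA preferred term."""

    primary_id: str
    pt: str

    def __post_init__(self) -> None:
        if not self.pt:
            raise ValueError("reaction PT must be non-empty")


@dataclass(slots=True)
class OutcomeRecord:
    primary_id: str
    outcome_code: str

    def __post_init__(self) -> None:
        if self.outcome_code not in OUTCOME_CODES:
            raise ValueError(f"invalid outcome code {self.outcome_code!r}")


@dataclass(slots=True)
class TherapyRecord:
    primary_id: str
    drug_seq: str
    start_date: dt.date | None = None


@dataclass(slots=True)
class IndicationRecord:
    primary_id: str
    drug_seq: str
    indication_pt: str

    def __post_init__(self) -> None:
        if not self.indication_pt:
            raise ValueError("indication PT must be non-empty")


def age_in_years(value: float | None, unit: str | None) -> float | None:
    """Normalize an (age_value, age_unit) pair to years.

    Units follow the FAERS ``age_cod`` convention: YR years, MON months,
    DY days.  An unrecognized unit yields ``None`` rather than a guess.
    """
    if value is None:
        return None
    if value < 0:
        return None
    unit = (unit or "YR").strip().upper()
    if unit in ("YR", "YEAR", "YEARS"):
        return float(value)
    if unit in ("MON", "MONTH", "MONTHS"):
        return float(value) / 12.0
    if unit in ("DY", "DAY", "DAYS"):
        return float(value) / 365.25
    return None


@dataclass(slots=True)
class CaseReport:
    """A deduplicated case: one surviving DEMO row with its child records.

    ``reactions`` holds unique uppercased PTs; ``matched_drug_seqs`` is filled
    by the primary-suspect filter with the drug_seq values of the suspect
    drugs that matched the target-name list.
    """

    demo: DemoRecord
    drugs: list[DrugRecord] = field(default_factory=list)
    reactions: list[ReacRecord] = field(default_factory=list)
    outcomes: list[OutcomeRecord] = field(default_factory=list)
    therapies: list[TherapyRecord] = field(default_factory=list)
    indications: list[IndicationRecord] = field(default_factory=list)
    matched_drug_seqs: frozenset[str] = frozenset()

    # convenience delegation to the demographic row
    @property
    def primary_id(self) -> str:
        return self.demo.primary_id

    @property
    def case_id(self) -> str:
        return self.demo.case_id

    @property
    def age_years(self) -> float | None:
        return age_in_years(self.demo.age_value, self.demo.age_unit)

    @property
    def pts(self) -> frozenset[str]:
        return frozenset(r.pt for r in self.reactions)

    def with_matches(self, seqs: frozenset[str]) -> "CaseReport":
        return replace(self, matched_drug_seqs=seqs)
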