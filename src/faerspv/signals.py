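"""Per-algorithm significance thresholds and the conjunctive signal rule.

A drug-event pair is a signal only when all four disproportionality methods
are simultaneously significant — the standard quartet of the spontaneous
reporting literature:

    ROR:   lower 95% CI bound > 1 and at least ``min_a`` reports
    PRR:   PRR >= 2, chi-square >= 4 and at least ``min_a`` reports
    BCPNN: IC025 > 0
    MGPS:  EBGM05 > 2
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path

from .bayesian import BcpnnResult, MgpsCell
from .frequentist import PrrResult, RorResult

__all__ = ["Thresholds", "SignalDecision", "decide_signal"]


@dataclass(frozen=True, slots=True)
class Thresholds:
    ror_ci_low_gt: float = 1.0
    prr_min: float = 2.0
    chisq_min: float = 4.0
    min_a: int = 3
    ic025_gt: float = 0.0
    ebgm05_gt: float = 2.0

    def __post_init__(self) -> None:
        if self.min_a < 1:
            raise ValueError("min_a must be at least 1")

    @classmethod
    def from_file(cls, path: str | Path) -> "Thresholds":
        """Read ``key = value`` lines; '#' starts a comment; unknown keys and
        unparseable values are hard errors naming the offender."""
        known = {f.name: f.type for f in fields(cls)}
        values: dict[str, float | int] = {}
        for i, line in enumerate(Path(path).read_text().splitlines()):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{i + 1}: expected 'key = value'")
            key, raw = (part.strip() for part in line.split("=", 1))
            if key not in known:
                raise ValueError(f"{path}:{i + 1}: unknown threshold {key!r}")
            try:
                values[key] = int(raw) if key == "min_a" else float(raw)
            except ValueError as err:
                raise ValueError(
                    f"{path}:{i + 1}: could not parse value {raw!r} for {key!r}"
                ) from err
        return cls(**values)


@dataclass(frozen=True, slots=True)
class SignalDecision:
    pass_ror: bool
    pass_prr: bool
    pass_bcpnn: bool
    pass_mgps: bool

    @property
    def is_signal(self) -> bool:
        return self.pass_ror and self.pass_prr and self.pass_bcpnn and self.pass_mgps


def decide_signal(
    r: RorResult,
    p: PrrResult,
    b: BcpnnResult,
    m: MgpsCell,
    a: int,
    th: Thresholds = Thresholds(),
) -> SignalDecision:
    """Apply the four per-algorithm rules; the signal verdict is their AND."""
    return SignalDecision(
        pass_ror=(a >= th.min_a and r.ci_low > th.ror_ci_low_gt),
        pass_prr=(a >= th.min_a and p.prr >= th.prr_min and p.chisq >= th.chisq_min),
        pass_bcpnn=(b.ic025 > th.ic025_gt),
        pass_mgps=(m.ebgm05 > th.ebgm05_gt),
    )
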