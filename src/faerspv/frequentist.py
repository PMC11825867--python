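"""Frequentist disproportionality: reporting odds ratio and proportional
reporting ratio with Wald intervals, plus the 2x2 chi-square statistic.

For the 2x2 table (a, b, c, d):

    ROR = (a d) / (b c),
    95% CI = exp(ln ROR +/- z sqrt(1/a + 1/b + 1/c + 1/d))

    PRR = [a / (a+b)] / [c / (c+d)],
    95% CI = exp(ln PRR +/- z sqrt(1/a - 1/(a+b) + 1/c - 1/(c+d)))

with the Yates-corrected chi-square, sum over cells of
(|O - E| - 0.5)^2 / E (truncated at zero), the convention of the spontaneous
reporting literature.  When any cell is zero the Haldane-Anscombe correction
adds 0.5 to all four cells before the ratios are formed; the result carries a
``corrected`` flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.stats import norm

from .contingency import ContingencyTable

__all__ = ["RorResult", "PrrResult", "compute_ror", "compute_prr", "chi_square"]


@dataclass(frozen=True, slots=True)
class RorResult:
    ror: float
    ci_low: float
    ci_high: float
    corrected: bool = False


@dataclass(frozen=True, slots=True)
class PrrResult:
    prr: float
    ci_low: float
    ci_high: float
    chisq: float
    corrected: bool = False


def _z_value(level: float) -> float:
    # 1.96 is the field's hard-wired 95% quantile; other levels are exact.
    if level == 0.95:
        return 1.96
    return float(norm.ppf(1.0 - (1.0 - level) / 2.0))


def _continuity(t: ContingencyTable) -> tuple[float, float, float, float, bool]:
    if t.n_total == 0:
        raise ValueError("contingency table is empty (N = 0)")
    cells = (t.a, t.b, t.c, t.d)
    if min(cells) == 0:
        return tuple(x + 0.5 for x in cells) + (True,)  # type: ignore[return-value]
    return (*map(float, cells), False)


def compute_ror(t: ContingencyTable, *, level: float = 0.95) -> RorResult:
    """Reporting odds ratio with a lognormal Wald interval."""
    a, b, c, d, corrected = _continuity(t)
    z = _z_value(level)
    ror = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    log_ror = math.log(ror)
    return RorResult(
        ror=ror,
        ci_low=math.exp(log_ror - z * se),
        ci_high=math.exp(log_ror + z * se),
        corrected=corrected,
    )


def chi_square(t: ContingencyTable, *, yates: bool = True) -> float:
    """Pearson chi-square on the 2x2, Yates-corrected by default.

    The corrected summand uses max(|O - E| - 0.5, 0), so perfectly
    independent tables score exactly zero.
    """
    n = t.n_total
    if n == 0:
        raise ValueError("contingency table is empty (N = 0)")
    row1, row2 = t.a + t.b, t.c + t.d
    col1, col2 = t.a + t.c, t.b + t.d
    if 0 in (row1, row2, col1, col2):
        return 0.0
    stat = 0.0
    for obs, er, ec in ((t.a, row1, col1), (t.b, row1, col2),
                        (t.c, row2, col1), (t.d, row2, col2)):
        exp = er * ec / n
        dev = abs(obs - exp)
        if yates:
            dev = max(dev - 0.5, 0.0)
        stat += dev * dev / exp
    return stat


def compute_prr(
    t: ContingencyTable, *, level: float = 0.95, yates: bool = True
) -> PrrResult:
    """Proportional reporting ratio, Wald interval and chi-square."""
    a, b, c, d, corrected = _continuity(t)
    z = _z_value(level)
    prr = (a / (a + b)) / (c / (c + d))
    se = math.sqrt(1 / a - 1 / (a + b) + 1 / c - 1 / (c + d))
    log_prr = math.log(prr)
    return PrrResult(
        prr=prr,
        ci_low=math.exp(log_prr - z * se),
        ci_high=math.exp(log_prr + z * se),
        chisq=chi_square(t, yates=yates),
        corrected=corrected,
    )
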