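"""Paired diagnostic-accuracy statistics.

Contingency tables pair an index test (OCT or VF call) against a
reference standard (MRI lesion presence).  From the four cells we
report sensitivity, specificity and positive/negative predictive
values; paired disagreement between two tests on the same subjects is
assessed with McNemar's test (exact binomial on the discordant pairs,
or the chi-square approximation with or without continuity correction).

Because published reports round the four statistics to two decimals,
`reconstruct_tables` searches exhaustively for every integer table of a
given total consistent with a rounded quadruple — an audit utility for
checking whether any cell counts can reproduce a published row.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

from scipy import stats as sps

__all__ = [
    "ContingencyTable",
    "DiagStats",
    "McNemarMethod",
    "McNemarResult",
    "UNDEFINED",
    "build_table",
    "diag_stats",
    "mcnemar",
    "reconstruct_tables",
    "round_half_up",
]

#: Explicit token for a statistic with a zero denominator.
UNDEFINED = None


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 paired counts: tp/fn/fp/tn with reference standard on the columns."""

    tp: int
    fn: int
    fp: int
    tn: int
    index_name: str = "index"
    reference_name: str = "reference"

    def __post_init__(self) -> None:
        cells = (self.tp, self.fn, self.fp, self.tn)
        if any(c < 0 or c != int(c) for c in cells):
            raise ValueError("contingency cells must be non-negative integers")
        if sum(cells) < 1:
            raise ValueError("empty contingency table")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


@dataclass(frozen=True)
class DiagStats:
    """The four accuracy statistics; None where the denominator is zero."""

    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None


class McNemarMethod(str, enum.Enum):
    EXACT = "exact"
    CHISQ = "chisq"
    CHISQ_CC = "chisq_cc"
    AUTO = "auto"  # exact when b+c < 25, else chisq


@dataclass(frozen=True)
class McNemarResult:
    b: int  # index+ / reference-
    c: int  # index- / reference+
    method: McNemarMethod
    statistic: float | None
    p_value: float


def build_table(
    index_calls: list[bool | None],
    reference_calls: list[bool | None],
    index_name: str = "index",
    reference_name: str = "reference",
) -> ContingencyTable:
    """Count paired boolean calls into a 2x2 table; pairs with a missing
    member are dropped (the drop count is recoverable from lengths)."""
    if len(index_calls) != len(reference_calls):
        raise ValueError("paired call lists must have equal length")
    tp = fn = fp = tn = 0
    for idx, ref in zip(index_calls, reference_calls):
        if idx is None or ref is None:
            continue
        if idx and ref:
            tp += 1
        elif idx and not ref:
            fp += 1
        elif ref:
            fn += 1
        else:
            tn += 1
    if tp + fn + fp + tn == 0:
        raise ValueError("no complete pairs to tabulate")
    return ContingencyTable(tp, fn, fp, tn, index_name, reference_name)


def _ratio(num: int, den: int) -> float | None:
    return num / den if den else UNDEFINED


def diag_stats(t: ContingencyTable) -> DiagStats:
    """sens = tp/(tp+fn); spec = tn/(tn+fp); ppv = tp/(tp+fp); npv = tn/(tn+fn)."""
    return DiagStats(
        sensitivity=_ratio(t.tp, t.tp + t.fn),
        specificity=_ratio(t.tn, t.tn + t.fp),
        ppv=_ratio(t.tp, t.tp + t.fp),
        npv=_ratio(t.tn, t.tn + t.fn),
    )


def mcnemar(
    index_calls: list[bool | None],
    reference_calls: list[bool | None],
    method: McNemarMethod | str = McNemarMethod.AUTO,
) -> McNemarResult:
    """McNemar's paired test on the discordant counts b and c.

    exact: p = min(1, 2 P(X <= min(b,c))), X ~ Binomial(b+c, 1/2).
    chisq: (b-c)^2/(b+c) on 1 df; chisq_cc uses (|b-c|-1)^2/(b+c).
    auto picks exact for b+c < 25, chisq otherwise.
    """
    method = McNemarMethod(method)
    t = build_table(index_calls, reference_calls)
    b, c = t.fp, t.fn  # index+/ref- and index-/ref+
    n_disc = b + c
    if method is McNemarMethod.AUTO:
        method = McNemarMethod.EXACT if n_disc < 25 else McNemarMethod.CHISQ
    if method is McNemarMethod.EXACT:
        if n_disc == 0:
            warnings.warn("no discordant pairs; exact McNemar p set to 1", RuntimeWarning)
            return McNemarResult(b, c, method, None, 1.0)
        p = min(1.0, 2.0 * sps.binom.cdf(min(b, c), n_disc, 0.5))
        return McNemarResult(b, c, method, None, float(p))
    if n_disc == 0:
        raise ZeroDivisionError("chi-square McNemar undefined with no discordant pairs")
    if method is McNemarMethod.CHISQ:
        stat = (b - c) ** 2 / n_disc
    else:
        stat = (abs(b - c) - 1) ** 2 / n_disc
    p = float(sps.chi2.sf(stat, df=1))
    return McNemarResult(b, c, method, float(stat), p)


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round half away from zero upward, matching printed-table formatting."""
    return float(Decimal(repr(x)).quantize(Decimal(10) ** -ndigits, rounding=ROUND_HALF_UP))


def _rounds_to(num: int, den: int, target: float | None) -> bool:
    if den == 0:
        return target is UNDEFINED
    if target is UNDEFINED:
        return False
    return math.isclose(round_half_up(num / den), target, abs_tol=1e-12)


def reconstruct_tables(stats: DiagStats, total_n: int) -> list[ContingencyTable]:
    """All integer tables with the given total whose four statistics round
    (half-up, 2 dp) to the given values.  Possibly empty; never raises on
    inconsistent inputs."""
    if total_n < 1:
        raise ValueError("total_n must be >= 1")
    out = []
    for tp in range(total_n + 1):
        for fn in range(total_n - tp + 1):
            if not _rounds_to(tp, tp + fn, stats.sensitivity):
                continue
            for fp in range(total_n - tp - fn + 1):
                tn = total_n - tp - fn - fp
                if not _rounds_to(tp, tp + fp, stats.ppv):
                    continue
                if not _rounds_to(tn, tn + fp, stats.specificity):
                    continue
                if not _rounds_to(tn, tn + fn, stats.npv):
                    continue
                out.append(ContingencyTable(tp, fn, fp, tn))
    return out
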