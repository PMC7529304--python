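"""Two-proportion chi-squared testing on 2x2 contingency tables.

The statistic follows the classical Pearson chi-squared on a 2x2 table with
optional Yates continuity correction,

    X^2 = N * (max(0, |ad - bc| - N/2))^2 / (r1 * r2 * c1 * c2)

with cells a = x1, b = n1 - x1, c = x2, d = n2 - x2, row totals
r1 = n1, r2 = n2 and column totals c1 = x1 + x2, c2 = N - c1. The p-value is
the upper tail of the chi-squared distribution with one degree of freedom,
evaluated through the survival function so that extreme values (down to
~1e-300) keep full relative accuracy. With the correction on, this matches
the default behaviour of R's ``prop.test`` for two groups.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Tuple

from scipy.stats import chi2

log = logging.getLogger(__name__)

NS_ALPHA = 0.05


@dataclass(frozen=True)
class ContingencyTable:
    """Successes/totals for two groups (pre-existing vs new with signature)."""

    x1: int
    n1: int
    x2: int
    n2: int

    def __post_init__(self):
        if not (0 <= self.x1 <= self.n1 and 0 <= self.x2 <= self.n2):
            raise ValueError(f"invalid contingency table {self}")
        if self.n1 < 1 or self.n2 < 1:
            raise ValueError("group totals must be >= 1")


def proportion_chisq(table: ContingencyTable,
                     continuity_correction: bool = True
                     ) -> Tuple[float, float]:
    """Chi-squared statistic and two-sided p for equality of two proportions.

    Returns ``(nan, nan)`` with a diagnostic when a marginal total is zero
    (all successes or all failures), where the statistic is undefined.
    """
    a, b = table.x1, table.n1 - table.x1
    c, d = table.x2, table.n2 - table.x2
    n1, n2 = table.n1, table.n2
    col1, col2 = a + c, b + d
    n_total = n1 + n2
    if col1 == 0 or col2 == 0:
        log.warning("proportion_chisq: zero marginal in %s; p undefined", table)
        return math.nan, math.nan
    cross = abs(a * d - b * c)
    if continuity_correction:
        cross = max(0.0, cross - n_total / 2.0)
    stat = n_total * cross * cross / (float(n1) * n2 * col1 * col2)
    return stat, float(chi2.sf(stat, df=1))


def format_p(p: float, ns_alpha: float = NS_ALPHA) -> str:
    """Display label: "NA" for undefined, "NS" at or above ``ns_alpha``,
    scientific with 3 significant digits below 0.001, else 3 decimals."""
    if p is None or math.isnan(p):
        return "NA"
    if p >= ns_alpha:
        return "NS"
    if p < 0.001:
        return f"{p:.2E}"
    return f"{p:.3f}"
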