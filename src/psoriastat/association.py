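"""Qualitative skin–joint / skin–nail association via 2×2 odds ratios.

Quantitative rank correlation (``psoriastat.ustat``) asks whether two
severities rise together; the odds ratio asks the weaker, qualitative
question of whether *any* involvement in one domain co-occurs with any
involvement in the other.  Counts are tallied into a 2×2 table, the OR
is ad/bc with a Haldane–Anscombe +0.5 correction when any cell is
empty, significance is Fisher's exact test (appropriate for the sparse
cells these cohorts produce) and the 95% CI is the Woolf log-OR
interval.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = ["ContingencyTable2x2", "OddsRatioResult", "build_table", "odds_ratio"]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts for involvement co-occurrence.

    Rows: first trait (e.g. skin) involved yes/no; columns: second trait
    (joint or nail) involved yes/no.  ``a``=both, ``b``=first only,
    ``c``=second only, ``d``=neither.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"cell {name} must be a non-negative integer, got {v!r}")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)


@dataclass(frozen=True)
class OddsRatioResult:
    or_estimate: float
    ci_low: float
    ci_high: float
    p_value: float
    corrected: bool  # True when the Haldane–Anscombe +0.5 was applied


def build_table(first_flags: Sequence[int], other_flags: Sequence[int]) -> ContingencyTable2x2:
    """Tally two equal-length binary involvement vectors into a 2×2 table."""
    x = np.asarray(first_flags)
    y = np.asarray(other_flags)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("flag vectors must be 1-D and of equal length")
    for v in (x, y):
        if not np.isin(v, (0, 1)).all():
            raise ValueError("flags must be binary (0/1)")
    a = int(np.sum((x == 1) & (y == 1)))
    b = int(np.sum((x == 1) & (y == 0)))
    c = int(np.sum((x == 0) & (y == 1)))
    d = int(np.sum((x == 0) & (y == 0)))
    return ContingencyTable2x2(a, b, c, d)


def odds_ratio(table: ContingencyTable2x2) -> OddsRatioResult:
    """Odds ratio with zero-cell correction, Fisher exact P, Woolf CI.

    The +0.5 continuity correction is applied to every cell iff any cell
    is zero; the corrected counts feed both the point estimate and the
    Woolf interval ``exp(log OR ± 1.96·√(Σ 1/cell))``.  Fisher's exact
    two-sided P always uses the raw integer counts.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    corrected = 0 in (a, b, c, d)
    if corrected:
        af, bf, cf, df = (x + 0.5 for x in (a, b, c, d))
    else:
        af, bf, cf, df = float(a), float(b), float(c), float(d)
    or_est = (af * df) / (bf * cf)
    se = np.sqrt(1.0 / af + 1.0 / bf + 1.0 / cf + 1.0 / df)
    z = stats.norm.ppf(0.975)
    ci_low = float(or_est * np.exp(-z * se))
    ci_high = float(or_est * np.exp(z * se))
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return OddsRatioResult(
        or_estimate=float(or_est),
        ci_low=ci_low,
        ci_high=ci_high,
        p_value=float(p),
        corrected=corrected,
    )
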