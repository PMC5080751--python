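"""Family sex-ratio statistics.

Sex ratio is the male fraction, males / (males + females).  Two inferential
tests: a Pearson chi-square (df = 1, no continuity correction) of pooled
counts against a 1:1 expectation, and Welch's unequal-variances t-test
comparing per-family ratios between system classes.  The continuity
correction is deliberately off: the uncorrected statistic is the one that
reproduces published pooled-count values from this kind of family data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .dataio import ParameterError


@dataclass(frozen=True)
class RatioSummary:
    family_id: str
    males: int
    females: int

    def __post_init__(self):
        if self.males < 0 or self.females < 0:
            raise ParameterError("negative offspring count")
        if self.males + self.females < 1:
            raise ParameterError("family with no offspring")

    @property
    def ratio(self) -> float:
        return self.males / (self.males + self.females)


def sex_ratio(males: int, females: int) -> float:
    """Male fraction of a brood."""
    return RatioSummary("", males, females).ratio


def chisq_1to1(males: int, females: int) -> tuple[float, float]:
    """Pearson chi-square (df=1, no continuity correction) vs a 1:1 ratio."""
    if males + females < 1:
        raise ParameterError("no offspring")
    n = males + females
    expected = n / 2.0
    chi2 = (males - expected) ** 2 / expected + (females - expected) ** 2 / expected
    p = float(stats.chi2.sf(chi2, df=1))
    return float(chi2), p


def welch_t(group_a, group_b) -> tuple[float, float, float]:
    """Welch's unequal-variances t-test on two groups of family sex ratios.

    Returns (t, Welch-Satterthwaite df, two-sided p).  Groups need >= 2
    values; two degenerate (zero-variance) groups with equal means give
    t = 0, p = 1.
    """
    a = np.asarray(list(group_a), dtype=float)
    b = np.asarray(list(group_b), dtype=float)
    if a.size < 2 or b.size < 2:
        raise ParameterError("each group needs at least 2 values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            return 0.0, float(a.size + b.size - 2), 1.0
        raise ParameterError("zero variance in both groups with unequal means")
    se2 = va / a.size + vb / b.size
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    df = se2**2 / ((va / a.size) ** 2 / (a.size - 1) + (vb / b.size) ** 2 / (b.size - 1))
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return float(t), float(df), p
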