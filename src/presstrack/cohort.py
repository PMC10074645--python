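"""Tag-effect return-rate comparison on 2x2 contingency tables.

Return rates of tagged vs control birds are compared with the classical
two-sample test for equality of proportions with Yates continuity
correction (equivalently the continuity-corrected chi-squared test on the
2x2 table) and with Fisher's exact test (two-sided, probability method).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["ContingencyTable2x2", "prop_test_continuity", "fisher_exact"]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts (a, b) = group-1 success/failure, (c, d) = group-2 success/failure."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for v in (self.a, self.b, self.c, self.d):
            if v < 0 or int(v) != v:
                raise ValueError("counts must be nonnegative integers")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("table is empty")

    @property
    def matrix(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=int)

    @property
    def proportions(self) -> tuple[float, float]:
        """Success proportion per group."""
        r1, r2 = self.a + self.b, self.c + self.d
        if r1 == 0 or r2 == 0:
            raise ValueError("both groups need at least one observation")
        return self.a / r1, self.c / r2


def prop_test_continuity(table: ContingencyTable2x2) -> dict:
    """Two-sample proportion test with continuity correction.

    chi2 = N * (max(|ad - bc| - N/2, 0))^2 / (r1 r2 c1 c2), p from chi2(1).
    """
    m = table.matrix
    if (m.sum(axis=0) == 0).any() or (m.sum(axis=1) == 0).any():
        raise ValueError("zero marginal: proportion test undefined")
    res = stats.chi2_contingency(m, correction=True)
    return {"chi2": float(res.statistic), "p": float(res.pvalue)}


def fisher_exact(table: ContingencyTable2x2) -> dict:
    """Two-sided Fisher exact test (probability method).

    Tables with a zero marginal are degenerate: p = 1 by convention,
    flagged.
    """
    m = table.matrix
    if (m.sum(axis=0) == 0).any() or (m.sum(axis=1) == 0).any():
        return {"p_two_sided": 1.0, "degenerate": True}
    res = stats.fisher_exact(m, alternative="two-sided")
    return {"p_two_sided": float(res.pvalue), "degenerate": False}
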