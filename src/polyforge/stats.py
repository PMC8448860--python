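"""Small statistical tests shared by every caller in the package.

Thin, validated wrappers around scipy with the reporting conventions used
throughout the analysis: two-sided Pearson chi-squared without continuity
correction, exact binomial tail sums, one-sided paired t, and the Bonferroni
genome-wide threshold.  p-values below double precision are additionally
reported with the conventional ``< 2.2e-16`` floor label.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as sps

#: conventional double-precision reporting floor for p-values
P_FLOOR = 2.2e-16

ONE_SIDED_GREATER = "one_sided_greater"
ONE_SIDED_LESS = "one_sided_less"
TWO_SIDED = "two_sided"
_SIDES = {ONE_SIDED_GREATER, ONE_SIDED_LESS, TWO_SIDED}


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts of a 2x2 contingency table (row-major: a b / c d)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        cells = (self.a, self.b, self.c, self.d)
        if any(int(x) != x or x < 0 for x in cells):
            raise ValueError("table entries must be non-negative integers")
        if sum(cells) == 0:
            raise ValueError("degenerate table: total count is zero")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)


@dataclass(frozen=True)
class TestResult:
    """Outcome of a hypothesis test.

    ``p_label`` mirrors the common reporting convention: exact value when
    representable, ``"< 2.2e-16"`` when the p-value underflows that floor.
    """

    statistic: float
    p_value: float
    sidedness: str
    method: str
    log10_p: float = field(default=float("nan"))

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p_value outside [0, 1]: {self.p_value}")
        if self.sidedness not in _SIDES:
            raise ValueError(f"unknown sidedness {self.sidedness!r}")

    @property
    def p_label(self) -> str:
        if self.p_value < P_FLOOR:
            return "< 2.2e-16"
        return format(self.p_value, ".4g")

    def to_row(self) -> dict:
        return {
            "test": self.method,
            "statistic": self.statistic,
            "p": self.p_value,
            "p_label": self.p_label,
            "sidedness": self.sidedness,
        }


def _log10_p(p: float, fallback: float) -> float:
    return math.log10(p) if p > 0 else fallback


def chi_squared_2x2(
    table: ContingencyTable2x2, *, continuity_correction: bool = False
) -> TestResult:
    """Pearson chi-squared test of independence on a 2x2 table (1 df).

    No Yates continuity correction by default; set
    ``continuity_correction=True`` to enable it.  Raises on a zero marginal
    row or column, where expected cells vanish.
    """
    arr = table.as_array()
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValueError("degenerate table: zero marginal row or column")
    stat, p, _, _ = sps.chi2_contingency(arr, correction=continuity_correction)
    # 1-df identity p = 2*Phi(-sqrt(x)): norm.logsf stays finite where
    # chi2.sf underflows
    logp = (math.log(2.0) + float(sps.norm.logsf(math.sqrt(stat)))) / math.log(10)
    return TestResult(float(stat), float(p), TWO_SIDED, "chi_squared_2x2", logp)


def exact_binomial(
    k: int, n: int, p0: float, sidedness: str = ONE_SIDED_GREATER
) -> TestResult:
    """Exact binomial test of ``k`` successes in ``n`` trials against ``p0``.

    ``one_sided_greater`` sums P(X >= k); ``one_sided_less`` sums P(X <= k);
    ``two_sided`` uses the standard small-probability-mass definition.
    """
    if not (0 < p0 < 1):
        raise ValueError(f"p0 must lie in (0, 1), got {p0}")
    if not (0 <= k <= n):
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    if sidedness not in _SIDES:
        raise ValueError(f"unknown sidedness {sidedness!r}")
    alt = {
        ONE_SIDED_GREATER: "greater",
        ONE_SIDED_LESS: "less",
        TWO_SIDED: "two-sided",
    }[sidedness]
    res = sps.binomtest(int(k), int(n), p0, alternative=alt)
    p = float(res.pvalue)
    if sidedness == ONE_SIDED_GREATER:
        logp = float(sps.binom.logsf(k - 1, n, p0)) / math.log(10)
    elif sidedness == ONE_SIDED_LESS:
        logp = float(sps.binom.logcdf(k, n, p0)) / math.log(10)
    else:
        logp = _log10_p(p, -320.0)
    return TestResult(float(k) / n if n else 0.0, p, sidedness, "exact_binomial", logp)


def paired_t_one_sided(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """One-sided paired t-test for mean(x - y) > 0.

    Constant differences (zero sample variance, including x == y) make the
    statistic undefined and raise ``ValueError("degenerate differences")``.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise ValueError("x and y must be equal-length 1-d sequences")
    if xa.size < 2:
        raise ValueError("need at least two pairs")
    d = xa - ya
    if np.ptp(d) == 0:
        raise ValueError("degenerate differences")
    stat, p = sps.ttest_rel(xa, ya, alternative="greater")
    return TestResult(
        float(stat), float(p), ONE_SIDED_GREATER, "paired_t_one_sided",
        _log10_p(float(p), -320.0),
    )


def bonferroni_threshold(alpha: float, n: int) -> float:
    """Genome-wide significance threshold alpha / n."""
    if not (0 < alpha < 1):
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    if int(n) != n or n < 1:
        raise ValueError(f"n must be a positive integer, got {n}")
    return alpha / n


def results_to_tsv(results: Sequence[TestResult], path) -> None:
    """Serialize test results to a TSV (test, statistic, p, p_label, sidedness)."""
    import pandas as pd

    pd.DataFrame([r.to_row() for r in results]).to_csv(path, sep="\t", index=False)
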