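"""Comparison statistics: chi-squared, Mann–Whitney U, pooled t-test.

Thin, validated wrappers around scipy.stats with the conventions used in the
cohort report: Pearson chi-squared without continuity correction by default
(the corrected 2x2 variant available behind a flag), a two-sided
Mann–Whitney U that is exact for small untied samples and a tie-corrected
normal approximation otherwise, and an independent-samples pooled-variance
t-test with explicit handling of zero-variance degenerate inputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Optional, Sequence

import numpy as np
from scipy import stats as sps

from .errors import DegenerateTableError, ValidationError

#: per-group size at or below which the Mann-Whitney p is exact (untied data)
MANN_WHITNEY_EXACT_MAX_N = 10


@dataclass(frozen=True)
class ContingencyTable:
    counts: tuple[tuple[int, ...], ...]
    row_labels: Optional[tuple[str, ...]] = None
    col_labels: Optional[tuple[str, ...]] = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts)
        if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
            raise ValidationError("contingency table needs at least 2 rows and 2 columns")
        if (arr < 0).any():
            raise ValidationError("contingency table counts must be non-negative")
        if arr.sum() <= 0:
            raise ValidationError("contingency table grand total must be positive")

    @classmethod
    def from_counts(cls, counts: Sequence[Sequence[int]],
                    row_labels: Optional[Sequence[str]] = None,
                    col_labels: Optional[Sequence[str]] = None) -> "ContingencyTable":
        return cls(
            counts=tuple(tuple(int(c) for c in row) for row in counts),
            row_labels=tuple(row_labels) if row_labels is not None else None,
            col_labels=tuple(col_labels) if col_labels is not None else None,
        )

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=float)

    @property
    def shape(self) -> tuple[int, int]:
        return (len(self.counts), len(self.counts[0]))


class ChiSquaredResult(NamedTuple):
    statistic: float
    df: int
    p_value: float


class MannWhitneyResult(NamedTuple):
    u: float
    p_value: float


class TTestResult(NamedTuple):
    t: float
    p_value: float


def chi_squared_test(table: ContingencyTable,
                     continuity_correction: bool = False) -> ChiSquaredResult:
    """Pearson chi-squared test of independence on an r x c table.

    The Yates continuity correction is applied only when requested *and* the
    table is 2x2.  A zero row or column margin makes expected counts
    degenerate and raises :class:`DegenerateTableError`.
    """
    arr = table.array
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise DegenerateTableError("contingency table has a zero row or column margin")
    apply_correction = continuity_correction and table.shape == (2, 2)
    stat, p, df, _ = sps.chi2_contingency(arr, correction=apply_correction)
    return ChiSquaredResult(statistic=float(stat), df=int(df), p_value=float(p))


def _has_ties(pooled: np.ndarray) -> bool:
    return len(np.unique(pooled)) < len(pooled)


def mann_whitney_u(group_a: Sequence[float], group_b: Sequence[float]) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U (U reported for ``group_a``, midrank ties).

    The p-value comes from exact enumeration when both groups have at most
    10 observations and the pooled data are untied, otherwise from the
    tie-corrected normal approximation with continuity correction.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both groups must be non-empty")
    small = a.size <= MANN_WHITNEY_EXACT_MAX_N and b.size <= MANN_WHITNEY_EXACT_MAX_N
    method = "exact" if small and not _has_ties(np.concatenate([a, b])) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return MannWhitneyResult(u=float(res.statistic), p_value=float(min(res.pvalue, 1.0)))


def two_sample_t_test(group_a: Sequence[float], group_b: Sequence[float]) -> TTestResult:
    """Independent-samples pooled-variance t-test, two-tailed.

    Zero pooled variance is handled explicitly: equal means give (0, 1);
    unequal means give an infinite statistic with p = 0.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("both groups need at least 2 observations")
    pooled_ss = ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
    if pooled_ss == 0:
        if a.mean() == b.mean():
            return TTestResult(t=0.0, p_value=1.0)
        return TTestResult(t=math.copysign(math.inf, a.mean() - b.mean()), p_value=0.0)
    res = sps.ttest_ind(a, b, equal_var=True)
    return TTestResult(t=float(res.statistic), p_value=float(res.pvalue))
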