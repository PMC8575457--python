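"""Normality-gated two-sample testing and Bonferroni correction.

Every group comparison in the pipeline uses the same decision rule: a
Shapiro-Wilk test on each sample at alpha = 0.05; if both look normal a
Welch two-sample t-test is run, otherwise a Wilcoxon rank-sum
(Mann-Whitney U) test. Tests are two-sided; multiple comparisons are
corrected with Bonferroni over an explicitly supplied family size.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats

SHAPIRO_ALPHA = 0.05
#: exact rank-sum null up to this per-group size (no ties); else normal
#: approximation with continuity correction
EXACT_RANKSUM_MAX_N = 25


class SampleSizeError(ValueError):
    """Sample too small for the requested test."""


@dataclass(frozen=True)
class TestOutcome:
    """Result of one gated two-sample comparison."""

    test_used: Literal["t", "wilcoxon"]
    statistic: float
    p_raw: float
    p_corrected: float
    normality_pA: float
    normality_pB: float


def _as_sample(x: Sequence[float], name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size < 3:
        raise SampleSizeError(f"sample {name} has {arr.size} values; need >=3 for the Shapiro gate")
    return arr


def _ranksum(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Wilcoxon rank-sum via Mann-Whitney U; exact null for small tie-free
    samples, otherwise normal approximation with continuity correction."""
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (max(x.size, y.size) <= EXACT_RANKSUM_MAX_N and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def gated_two_sample_test(
    x: Sequence[float],
    y: Sequence[float],
    family_size: int = 1,
    gate_alpha: float = SHAPIRO_ALPHA,
) -> TestOutcome:
    """Shapiro-gated two-sample comparison, two-sided.

    Welch's t-test when both samples pass the normality gate
    (Shapiro p >= ``gate_alpha`` for each), Wilcoxon rank-sum otherwise.
    The returned ``p_corrected`` is Bonferroni for ``family_size``
    comparisons.
    """
    xa = _as_sample(x, "x")
    ya = _as_sample(y, "y")
    p_norm_x = float(stats.shapiro(xa).pvalue)
    p_norm_y = float(stats.shapiro(ya).pvalue)
    if p_norm_x >= gate_alpha and p_norm_y >= gate_alpha:
        res = stats.ttest_ind(xa, ya, equal_var=False)
        used: Literal["t", "wilcoxon"] = "t"
        statistic, p_raw = float(res.statistic), float(res.pvalue)
    else:
        used = "wilcoxon"
        statistic, p_raw = _ranksum(xa, ya)
    return TestOutcome(
        test_used=used,
        statistic=statistic,
        p_raw=p_raw,
        p_corrected=min(1.0, family_size * p_raw),
        normality_pA=p_norm_x,
        normality_pB=p_norm_y,
    )


def bonferroni(p_values: Sequence[float], m: int) -> list[float]:
    """Bonferroni correction: p -> min(1, m * p); order-preserving."""
    pvals = list(p_values)
    if m < len(pvals):
        raise ValueError(f"family size m={m} smaller than number of p-values ({len(pvals)})")
    for p in pvals:
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"p-value {p} outside [0, 1]")
    return [min(1.0, m * p) for p in pvals]
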