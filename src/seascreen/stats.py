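"""Inferential comparisons: paired species t-tests and rank correlations.

Species are compared at shared sites with classical paired t-tests on the
differences (two-sided p from the t distribution, n-1 df), with a
Bonferroni-corrected significance threshold across the family of
comparisons.  Normality of the differences is checked (Shapiro-Wilk) and
reported as a warning only — it never gates the test.  Spatial and
temporal trends use Spearman rank correlation with average-rank tie
handling; collection dates enter as days-since-epoch ordinals (Spearman is
invariant to any strictly monotone encoding).
"""

from __future__ import annotations

import datetime as _dt
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as _sps

__all__ = [
    "PairedComparison",
    "paired_t",
    "rank_correlation",
    "pct_higher",
    "bonferroni_alpha",
    "date_ordinal",
]


@dataclass(frozen=True)
class PairedComparison:
    analyte_id: str
    n_pairs: int
    mean_diff: float  # mean(b - a)
    t_stat: float
    p_value: float
    alpha: float  # corrected significance threshold
    pct_higher: float  # 100*(meanB - meanA)/meanA
    normality_p: float | None  # Shapiro-Wilk p on the differences
    n_dropped: int = 0  # incomplete pairs removed

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


def bonferroni_alpha(family_alpha: float = 0.05, n_comparisons: int = 1) -> float:
    """Per-comparison threshold alpha / k (0.05 over 3 tests -> 0.0167)."""
    if n_comparisons < 1:
        raise ValueError("need at least one comparison")
    return family_alpha / n_comparisons


def paired_t(
    a: Sequence[float],
    b: Sequence[float],
    *,
    analyte_id: str = "",
    alpha: float = 0.05,
) -> PairedComparison:
    """Paired t-test of species B against species A at shared sites.

    Incomplete pairs (either member missing/NaN) are dropped and counted.
    Swapping a and b negates t and mean_diff and preserves p.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    ok = ~(np.isnan(a) | np.isnan(b))
    n_dropped = int((~ok).sum())
    a, b = a[ok], b[ok]
    n = len(a)
    if n < 2:
        raise ValueError(f"need at least 2 complete pairs, have {n}")
    diffs = b - a
    if np.allclose(diffs, diffs[0]) and math.isclose(diffs[0], 0.0, abs_tol=0.0):
        t_stat, p = 0.0, 1.0
    else:
        res = _sps.ttest_rel(b, a)
        t_stat, p = float(res.statistic), float(res.pvalue)
        if math.isnan(t_stat):  # zero-variance nonzero differences
            t_stat, p = math.copysign(math.inf, diffs[0]), 0.0
    normality_p = None
    if n >= 3 and np.ptp(diffs) > 0:
        normality_p = float(_sps.shapiro(diffs).pvalue)
    mean_a = float(a.mean())
    return PairedComparison(
        analyte_id=analyte_id,
        n_pairs=n,
        mean_diff=float(diffs.mean()),
        t_stat=t_stat,
        p_value=p,
        alpha=alpha,
        pct_higher=pct_higher(mean_a, float(b.mean())) if mean_a > 0 else math.nan,
        normality_p=normality_p,
        n_dropped=n_dropped,
    )


def rank_correlation(
    values: Sequence[float],
    covariate: Sequence[float],
) -> tuple[float, float]:
    """Spearman rho (average-rank ties) and two-sided p.

    A constant covariate (or constant values) has no defined rank
    correlation: returns (nan, nan).
    """
    values = np.asarray(values, dtype=float)
    covariate = np.asarray(covariate, dtype=float)
    if len(values) != len(covariate):
        raise ValueError("values and covariate must have equal length")
    if len(values) < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(covariate) == 0 or np.ptp(values) == 0:
        return (math.nan, math.nan)
    res = _sps.spearmanr(values, covariate)
    return (float(res.statistic), float(res.pvalue))


def pct_higher(mean_a: float, mean_b: float) -> float:
    """Percent by which B exceeds A: ``100*(meanB - meanA)/meanA``."""
    if mean_a <= 0:
        raise ValueError(f"baseline mean must be positive, got {mean_a}")
    return 100.0 * (mean_b - mean_a) / mean_a


def date_ordinal(dates: Sequence[_dt.date]) -> np.ndarray:
    """Days-since-epoch ordinals for rank-correlating collection dates."""
    return np.array([d.toordinal() for d in dates], dtype=float)
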