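"""Left-censored substitution policies and censored summary statistics.

Concentrations reported below the lower limit of quantitation (LOQ) are
left-censored.  Before any mean, SD, median or sum, each censored value is
replaced by ``factor * LOQ`` under one of three substitution policies:

* ``zero``     (factor 0)   — least conservative for a consumer,
* ``half_loq`` (factor 0.5) — the moderately conservative default,
* ``full_loq`` (factor 1)   — most conservative.

Because substitution is linear, the zero and full-LOQ results bracket the
half-LOQ result for any monotone statistic; :func:`bound_interval` exposes
that bracket directly.  No likelihood-based censored estimators are used —
substitution is the method being reproduced.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np

from .survey import Measurement

__all__ = [
    "SubstitutionPolicy",
    "CensoredSummary",
    "substitute",
    "summarize",
    "bound_interval",
]


class SubstitutionPolicy(Enum):
    ZERO = 0.0
    HALF_LOQ = 0.5
    FULL_LOQ = 1.0

    @property
    def factor(self) -> float:
        return self.value

    @classmethod
    def parse(cls, token: "str | SubstitutionPolicy") -> "SubstitutionPolicy":
        if isinstance(token, cls):
            return token
        key = str(token).strip().lower()
        aliases = {
            "zero": cls.ZERO,
            "0": cls.ZERO,
            "half": cls.HALF_LOQ,
            "half_loq": cls.HALF_LOQ,
            "full": cls.FULL_LOQ,
            "full_loq": cls.FULL_LOQ,
            "loq": cls.FULL_LOQ,
        }
        try:
            return aliases[key]
        except KeyError:
            raise ValueError(f"unknown substitution policy {token!r}") from None


@dataclass(frozen=True)
class CensoredSummary:
    """Summary statistics of one analyte series under one policy.

    ``pct_above_loq`` is stored unrounded (display rounds to the nearest
    integer).  ``mean_loq_of_censored`` is the mean LOQ over the censored
    entries only (``None`` when nothing is censored).  ``degenerate`` flags
    an n=1 series whose SD is reported as 0 by convention.
    """

    n: int
    pct_above_loq: float
    mean_loq_of_censored: float | None
    mean: float
    sd: float
    median: float
    min: float
    max: float
    policy: SubstitutionPolicy
    degenerate: bool = False


def _check_homogeneous(
    measurements: Sequence[Measurement], *, same_analyte: bool = True
) -> None:
    if not measurements:
        raise ValueError("empty measurement series")
    units = {m.unit for m in measurements}
    bases = {m.basis for m in measurements}
    if len(units) > 1:
        raise ValueError(f"mixed units in series: {sorted(u.value for u in units)}")
    if len(bases) > 1:
        raise ValueError(f"mixed bases in series: {sorted(b.value for b in bases)}")
    if same_analyte:
        analytes = {m.analyte_id for m in measurements}
        if len(analytes) > 1:
            raise ValueError(f"mixed analytes in series: {sorted(analytes)}")


def substitute(
    measurements: Sequence[Measurement],
    policy: SubstitutionPolicy | str,
    *,
    same_analyte: bool = True,
) -> np.ndarray:
    """Numeric series with censored entries replaced by ``factor * LOQ``.

    All measurements must share analyte, unit and basis (``same_analyte``
    is relaxed by congener-group summation, which mixes analytes of one
    sample on purpose); uncensored values pass through unchanged.
    """
    policy = SubstitutionPolicy.parse(policy)
    _check_homogeneous(measurements, same_analyte=same_analyte)
    out = np.empty(len(measurements), dtype=float)
    for i, m in enumerate(measurements):
        out[i] = policy.factor * m.loq if m.censored else m.value
    return out


def summarize(
    measurements: Sequence[Measurement],
    policy: SubstitutionPolicy | str = SubstitutionPolicy.HALF_LOQ,
) -> CensoredSummary:
    """Censored summary: n, percent above LOQ, mean LOQ of censored entries,
    and mean/SD/median/range under the active policy.

    SD uses the n-1 denominator; the median of an even-length series is the
    midpoint of the two central order statistics.  A single-value series is
    reported with SD 0 and ``degenerate=True`` rather than failing.
    """
    policy = SubstitutionPolicy.parse(policy)
    values = substitute(measurements, policy)
    n = len(values)
    n_cens = sum(m.censored for m in measurements)
    loqs = [m.loq for m in measurements if m.censored]
    degenerate = n == 1
    return CensoredSummary(
        n=n,
        pct_above_loq=100.0 * (n - n_cens) / n,
        mean_loq_of_censored=float(np.mean(loqs)) if loqs else None,
        mean=float(np.mean(values)),
        sd=0.0 if degenerate else float(np.std(values, ddof=1)),
        median=float(np.median(values)),
        min=float(np.min(values)),
        max=float(np.max(values)),
        policy=policy,
        degenerate=degenerate,
    )


def bound_interval(
    measurements: Sequence[Measurement],
    statistic: str = "mean",
) -> tuple[float, float]:
    """(value under zero policy, value under full-LOQ policy).

    The half-LOQ value always lies inside the closed interval; for mean and
    sum it is exactly the midpoint (substitution is linear).
    """
    if statistic not in {"mean", "sum"}:
        raise ValueError(f"statistic must be 'mean' or 'sum', got {statistic!r}")
    fn = np.mean if statistic == "mean" else np.sum
    low = float(fn(substitute(measurements, SubstitutionPolicy.ZERO)))
    high = float(fn(substitute(measurements, SubstitutionPolicy.FULL_LOQ)))
    return (low, high)
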