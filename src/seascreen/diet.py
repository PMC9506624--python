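"""Per-portion contaminant amounts and the mean + 2 SD outlier rule.

Seaweed is compared with common foods on a per-portion basis: seaweed
portions are 5 g dry weight, food portions are their customary wet-weight
serving sizes, and the two bases are never mixed without labelling.  A
concentration C (mg/kg) in a portion of mass p (g) delivers C * p / 1000
mg of contaminant.

Per species and contaminant, sites whose per-portion amount exceeds the
across-site mean + 2 SD are flagged as statistical outliers (single pass
by default), and a trimmed mean/SD excluding the flagged sites is reported
for the remaining-sites bar.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .registries import FoodItem

__all__ = [
    "PortionAmount",
    "OutlierFlag",
    "OutlierReport",
    "SEAWEED_PORTION_G_DW",
    "per_portion",
    "food_per_portion",
    "flag_outliers",
]

SEAWEED_PORTION_G_DW = 5.0


@dataclass(frozen=True)
class PortionAmount:
    item_name: str
    item_kind: str  # 'seaweed_site' | 'food'
    contaminant: str
    mass_per_portion: float  # mg per portion
    portion_basis: str  # 'g DW' for seaweed, 'g WW' for foods

    def __post_init__(self):
        if self.mass_per_portion < 0:
            raise ValueError("mass_per_portion must be >= 0")


def per_portion(conc: float, portion_mass: float) -> float:
    """Contaminant mass per portion, mg: ``conc [mg/kg] * portion [g] / 1000``.

    The caller is responsible for matching bases (dry-weight concentration
    with a dry-weight portion mass, wet with wet).
    """
    if conc < 0 or portion_mass <= 0:
        raise ValueError("need conc >= 0 and portion_mass > 0")
    return conc * portion_mass * 1e-3


def food_per_portion(food: FoodItem) -> PortionAmount:
    return PortionAmount(
        item_name=food.food_name,
        item_kind="food",
        contaminant=food.contaminant,
        mass_per_portion=per_portion(food.conc, food.portion_mass),
        portion_basis="g WW",
    )


@dataclass(frozen=True)
class OutlierFlag:
    site_code: str
    species: str
    contaminant: str
    flagged: bool
    value: float
    threshold: float  # mean + 2*SD over all sites


@dataclass(frozen=True)
class OutlierReport:
    flags: tuple[OutlierFlag, ...]
    threshold: float | None  # None when n < 3 (no flagging performed)
    trimmed_mean: float | None  # over unflagged sites
    trimmed_sd: float | None
    note: str = ""

    @property
    def flagged_sites(self) -> tuple[str, ...]:
        return tuple(f.site_code for f in self.flags if f.flagged)


def flag_outliers(
    amounts: Mapping[str, float],
    species: str,
    contaminant: str,
    *,
    iterate: bool = False,
) -> OutlierReport:
    """Flag sites whose per-portion amount strictly exceeds mean + 2 SD.

    ``amounts`` maps site_code -> mg/portion for one species x contaminant.
    The threshold uses the sample SD (n-1) over *all* sites, computed once
    (single pass); with ``iterate=True`` the rule is reapplied to the
    unflagged remainder until stable.  A constant series flags nothing
    (threshold equals the value; the comparison is strict), and fewer than
    3 sites yields an informational no-flagging report.  Single-pass
    flagging can miss visually obvious outliers when one large value
    inflates the SD — that is a property of the rule, not a bug.
    """
    sites = sorted(amounts)
    values = np.array([amounts[s] for s in sites], dtype=float)
    n = len(values)
    if n < 3:
        flags = tuple(
            OutlierFlag(s, species, contaminant, False, amounts[s], np.nan)
            for s in sites
        )
        return OutlierReport(
            flags=flags,
            threshold=None,
            trimmed_mean=float(values.mean()) if n else None,
            trimmed_sd=float(values.std(ddof=1)) if n > 1 else None,
            note=f"n={n} < 3 sites: no outlier flagging performed",
        )

    active = np.ones(n, dtype=bool)
    while True:
        mean = values[active].mean()
        sd = values[active].std(ddof=1)
        threshold = mean + 2.0 * sd
        newly = active & (values > threshold)
        if not iterate or not newly.any():
            flagged = values > threshold if not iterate else ~active | newly
            break
        active &= ~newly

    keep = ~flagged
    flags = tuple(
        OutlierFlag(s, species, contaminant, bool(f), float(v), float(threshold))
        for s, v, f in zip(sites, values, flagged)
    )
    return OutlierReport(
        flags=flags,
        threshold=float(threshold),
        trimmed_mean=float(values[keep].mean()) if keep.any() else None,
        trimmed_sd=float(values[keep].std(ddof=1)) if keep.sum() > 1 else None,
    )
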