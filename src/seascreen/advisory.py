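"""Site-specific consumption advisories.

Where a measured concentration exceeds its reference level, the screening
equations are inverted for the consumption rate: setting the screening
level equal to the measured concentration and solving for CR gives the
maximum daily intake (g DW/day) at which the reference is not exceeded::

    rate = baseline_cr * reference / conc

Per site, species and date, the rate is computed for each contaminant in
the advisory set and the *binding* (minimum) rate identifies the
contaminant driving the advisory.  Rates at or above the baseline are
reported as ">= baseline"; display rounds half-to-even to one decimal, but
binding/flagging decisions use the unrounded values (so a rate that rounds
to the baseline can still bind).
"""

from __future__ import annotations

import datetime as _dt
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .censoring import SubstitutionPolicy
from .registries import RegulatoryLimit, lowest_limit
from .screening import ScreeningLevel
from .survey import SurveyTable
from .units import Basis

__all__ = [
    "AdvisoryRow",
    "AdvisoryReference",
    "DEFAULT_ADVISORY_REFS",
    "max_rate",
    "round_rate",
    "format_rate",
    "build_advisory",
]


def max_rate(conc: float, reference: float, baseline_cr: float = 5.0) -> float:
    """Maximum consumption rate (g DW/day) from one concentration.

    ``conc`` and ``reference`` in mg/kg DW.  A zero (or censored-at-zero)
    concentration is unbounded: returns ``inf`` (displayed as ">= baseline").
    The returned value is uncapped; capping happens at display time.
    """
    if conc < 0:
        raise ValueError(f"concentration must be >= 0, got {conc}")
    if reference <= 0:
        raise ValueError(f"reference must be > 0, got {reference}")
    if baseline_cr <= 0:
        raise ValueError(f"baseline_cr must be > 0, got {baseline_cr}")
    if conc == 0:
        return math.inf
    return baseline_cr * reference / conc


def round_rate(rate: float, ndigits: int = 1) -> float:
    """Round half-to-even to one decimal, as reported."""
    return round(rate, ndigits)


def format_rate(rate: float, baseline_cr: float = 5.0) -> str:
    """Display form: '>=5' when the unrounded rate meets the baseline."""
    if rate >= baseline_cr:
        return f">={baseline_cr:g}"
    return f"{round_rate(rate):.1f}"


@dataclass(frozen=True)
class AdvisoryReference:
    """How one advisory contaminant is referenced.

    kind: 'sl_rfd', 'sl_csf' or 'limit'; for 'limit', ``jurisdiction``
    selects the international limit (None = lowest applicable).
    """

    kind: str
    jurisdiction: str | None = None

    def __post_init__(self):
        if self.kind not in {"sl_rfd", "sl_csf", "limit"}:
            raise ValueError(f"unknown advisory reference kind {self.kind!r}")


# Default advisory set: noncancer levels for Cd and (methyl-surrogate) Hg,
# cancer levels for BaP and the PCB sum, and the French international limit
# for Pb (which has no RfD/CSF).
DEFAULT_ADVISORY_REFS: dict[str, AdvisoryReference] = {
    "Cd": AdvisoryReference("sl_rfd"),
    "Hg": AdvisoryReference("sl_rfd"),
    "Pb": AdvisoryReference("limit", "France"),
    "BaP": AdvisoryReference("sl_csf"),
    "SUM_PCB40": AdvisoryReference("sl_csf"),
}


@dataclass(frozen=True)
class AdvisoryRow:
    site_code: str
    site_name: str
    species: str
    collection_date: _dt.date
    per_analyte_rate: Mapping[str, float]  # unrounded g DW/day (may be inf)
    missing_analytes: tuple[str, ...]  # advisory analytes absent from survey
    binding_analyte: str | None
    binding_rate: float
    baseline_cr: float

    def display(self) -> dict[str, str]:
        out = {a: format_rate(r, self.baseline_cr) for a, r in self.per_analyte_rate.items()}
        for a in self.missing_analytes:
            out[a] = "---"
        return out


def _resolve_reference(
    analyte_id: str,
    ref: AdvisoryReference,
    levels: Mapping[str, ScreeningLevel],
    limits: Mapping[str, list[RegulatoryLimit]],
    moisture: float | None,
) -> float | None:
    if ref.kind in {"sl_rfd", "sl_csf"}:
        sl = levels.get(analyte_id)
        if sl is None:
            return None
        return sl.sl_rfd if ref.kind == "sl_rfd" else sl.sl_csf
    if ref.jurisdiction is not None:
        for lim in limits.get(analyte_id, []):
            if lim.jurisdiction == ref.jurisdiction and lim.basis is Basis.DRY:
                return lim.limit_value
        return None
    resolved = lowest_limit(
        limits, analyte_id, Basis.DRY, moisture_fraction=moisture
    )
    return None if resolved is None else resolved.value


def build_advisory(
    survey: SurveyTable,
    levels: Mapping[str, ScreeningLevel],
    limits: Mapping[str, list[RegulatoryLimit]] | None = None,
    *,
    advisory_refs: Mapping[str, AdvisoryReference] | None = None,
    policy: SubstitutionPolicy | str = SubstitutionPolicy.HALF_LOQ,
    baseline_cr: float = 5.0,
    species_moisture: Mapping[str, float] | None = None,
) -> list[AdvisoryRow]:
    """One advisory row per site x species x date.

    The survey must already be aggregated (group-sum rows present) and in
    canonical mg/kg DW.  Censored concentrations enter at the policy's
    substituted value (the default half-LOQ matches how reported PCB sums
    are built).  Advisory analytes absent from a sample are listed in
    ``missing_analytes`` and shown as '---'.  ``binding_analyte`` is set
    only when the minimum unrounded rate falls below the baseline.
    """
    policy = SubstitutionPolicy.parse(policy)
    advisory_refs = dict(advisory_refs or DEFAULT_ADVISORY_REFS)
    limits = limits or {}
    species_moisture = species_moisture or {}
    rows: list[AdvisoryRow] = []
    for site, species, date in survey.samples():
        sample = [
            m
            for m in survey.measurements
            if (m.site_code, m.species, m.collection_date) == (site, species, date)
        ]
        by_id = {m.analyte_id: m for m in sample}
        rates: dict[str, float] = {}
        missing: list[str] = []
        for analyte_id, ref in advisory_refs.items():
            m = by_id.get(analyte_id)
            if m is None:
                missing.append(analyte_id)
                continue
            moisture = (
                m.moisture_fraction
                if m.moisture_fraction is not None
                else species_moisture.get(species)
            )
            reference = _resolve_reference(analyte_id, ref, levels, limits, moisture)
            if reference is None:
                missing.append(analyte_id)
                continue
            conc = policy.factor * m.loq if m.censored else m.value
            rates[analyte_id] = max_rate(conc, reference, baseline_cr)
        binding_rate = min(rates.values()) if rates else math.inf
        binding_analyte = None
        if rates and binding_rate < baseline_cr:
            binding_analyte = min(
                (a for a, r in rates.items() if r == binding_rate)
            )
        rows.append(
            AdvisoryRow(
                site_code=site,
                site_name=sample[0].site_name,
                species=species,
                collection_date=date,
                per_analyte_rate=rates,
                missing_analytes=tuple(missing),
                binding_analyte=binding_analyte,
                binding_rate=binding_rate,
                baseline_cr=baseline_cr,
            )
        )
    return rows
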