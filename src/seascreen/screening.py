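"""Risk-based screening levels and exceedance evaluation.

Two tissue-concentration screening levels (mg contaminant / kg dry weight
of seaweed) are derived from oral toxicity constants at assumed adult
exposure parameters (body weight BW in kg, consumption rate CR in g dry
weight per day, acceptable excess lifetime cancer risk ARL):

noncancer (reference dose RfD, mg/kg-day)::

    SL_RfD = RfD * BW / CR * 1000

cancer (slope factor CSF, (mg/kg-day)^-1)::

    SL_CSF = (ARL * BW / CSF) / (CR / 1000)

The factor 1000 converts the g/day consumption rate to kg/day.  At the
defaults (BW=80, CR=5, ARL=1e-6) both reduce to SL_RfD = 16000*RfD and
SL_CSF = 0.016/CSF mg/kg DW.

Measured concentrations are compared with these levels and with the lowest
applicable international limit; "exceeds" uses strict inequality on the
unrounded values.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass
from typing import Mapping, Sequence

from .censoring import SubstitutionPolicy
from .registries import (
    ExposureParams,
    RegulatoryLimit,
    ResolvedLimit,
    ToxRef,
    lowest_limit,
)
from .survey import Measurement, SurveyTable
from .units import Basis

__all__ = [
    "ScreeningLevel",
    "ExceedanceRecord",
    "NoScreeningLevel",
    "sl_rfd",
    "sl_csf",
    "screening_levels",
    "evaluate",
    "pct_of_reference",
]


class NoScreeningLevel(ValueError):
    """The requested kind of screening level does not exist for this analyte."""


def sl_rfd(toxref: ToxRef, params: ExposureParams | None = None) -> float:
    """Noncancer screening level, mg/kg DW: ``RfD * BW / CR * 1000``."""
    params = params or ExposureParams()
    if toxref.rfd is None:
        raise NoScreeningLevel(f"{toxref.analyte_id}: no RfD on record")
    return toxref.rfd * params.bw / params.cr * 1000.0


def sl_csf(toxref: ToxRef, params: ExposureParams | None = None) -> float:
    """Cancer screening level, mg/kg DW: ``(ARL * BW / CSF) / (CR / 1000)``.

    The allowed daily dose ARL*BW/CSF (mg/day) divided by consumption in
    kg/day.
    """
    params = params or ExposureParams()
    if toxref.csf is None or toxref.csf == 0:
        raise NoScreeningLevel(f"{toxref.analyte_id}: no CSF on record")
    return (params.arl * params.bw / toxref.csf) / (params.cr / 1000.0)


@dataclass(frozen=True)
class ScreeningLevel:
    """Both screening levels (when defined) for one analyte, mg/kg DW."""

    analyte_id: str
    sl_rfd: float | None
    sl_csf: float | None
    params: ExposureParams
    surrogate_note: str = ""

    def __post_init__(self):
        if self.sl_rfd is None and self.sl_csf is None:
            raise NoScreeningLevel(f"{self.analyte_id}: no screening level at all")

    @property
    def governing(self) -> float:
        """The stricter (lower) of the defined levels."""
        return min(v for v in (self.sl_rfd, self.sl_csf) if v is not None)


def screening_levels(
    toxrefs: Mapping[str, ToxRef],
    params: ExposureParams | None = None,
) -> dict[str, ScreeningLevel]:
    """Screening levels for every analyte in the toxicity registry."""
    params = params or ExposureParams()
    out = {}
    for analyte_id, ref in toxrefs.items():
        out[analyte_id] = ScreeningLevel(
            analyte_id=analyte_id,
            sl_rfd=None if ref.rfd is None else sl_rfd(ref, params),
            sl_csf=None if ref.csf is None or ref.csf == 0 else sl_csf(ref, params),
            params=params,
            surrogate_note=ref.surrogate_note,
        )
    return out


@dataclass(frozen=True)
class ExceedanceRecord:
    site_code: str
    species: str
    collection_date: _dt.date
    analyte_id: str
    conc: float  # mg/kg DW under the active policy
    reference_kind: str  # sl_rfd | sl_csf | international | none
    reference_value: float | None
    jurisdiction: str  # for international references
    exceeds: bool
    ratio: float | None  # conc / reference
    policy: SubstitutionPolicy
    surrogate_note: str = ""


def evaluate(
    survey: SurveyTable,
    levels: Mapping[str, ScreeningLevel],
    limits: Mapping[str, list[RegulatoryLimit]] | None = None,
    policy: SubstitutionPolicy | str = SubstitutionPolicy.HALF_LOQ,
    *,
    species_moisture: Mapping[str, float] | None = None,
    limit_log: list[str] | None = None,
) -> list[ExceedanceRecord]:
    """One record per measurement x applicable reference.

    The survey must be in canonical mg/kg DW form.  Censored measurements
    are evaluated at the substitution policy's value, with the policy
    recorded.  Analytes lacking any reference produce an informational
    record with ``reference_kind='none'``; "exceeds" is strict
    (conc > reference), so a concentration exactly at its reference does
    not flag.
    """
    policy = SubstitutionPolicy.parse(policy)
    species_moisture = species_moisture or {}
    limits = limits or {}
    records: list[ExceedanceRecord] = []
    for m in survey.measurements:
        if m.basis is not Basis.DRY:
            raise ValueError(f"{m.key()}: evaluate() expects dry-weight basis")
        conc = policy.factor * m.loq if m.censored else m.value
        refs: list[tuple[str, float, str, str]] = []
        sl = levels.get(m.analyte_id)
        if sl is not None:
            if sl.sl_rfd is not None:
                refs.append(("sl_rfd", sl.sl_rfd, "", sl.surrogate_note))
            if sl.sl_csf is not None:
                refs.append(("sl_csf", sl.sl_csf, "", sl.surrogate_note))
        moisture = (
            m.moisture_fraction
            if m.moisture_fraction is not None
            else species_moisture.get(m.species)
        )
        resolved: ResolvedLimit | None = lowest_limit(
            limits,
            m.analyte_id,
            Basis.DRY,
            moisture_fraction=moisture,
            log=limit_log,
        )
        if resolved is not None:
            refs.append(
                ("international", resolved.value, resolved.limit.jurisdiction, "")
            )
        if not refs:
            records.append(
                ExceedanceRecord(
                    site_code=m.site_code,
                    species=m.species,
                    collection_date=m.collection_date,
                    analyte_id=m.analyte_id,
                    conc=conc,
                    reference_kind="none",
                    reference_value=None,
                    jurisdiction="",
                    exceeds=False,
                    ratio=None,
                    policy=policy,
                )
            )
            continue
        for kind, ref_value, jurisdiction, note in refs:
            ratio = conc / ref_value
            records.append(
                ExceedanceRecord(
                    site_code=m.site_code,
                    species=m.species,
                    collection_date=m.collection_date,
                    analyte_id=m.analyte_id,
                    conc=conc,
                    reference_kind=kind,
                    reference_value=ref_value,
                    jurisdiction=jurisdiction,
                    exceeds=conc > ref_value,
                    ratio=ratio,
                    policy=policy,
                    surrogate_note=note,
                )
            )
    return records


def pct_of_reference(conc: float, reference: float) -> float:
    """``100 * conc / reference`` (display rounds; internal value exact)."""
    if reference <= 0:
        raise ValueError(f"reference must be positive, got {reference}")
    return 100.0 * conc / reference
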