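"""Unit and basis algebra for tissue concentrations.

Concentrations are mass-of-contaminant per mass-of-tissue, expressed either
in mg/kg or µg/kg, on a dry-weight (DW) or wet-weight (WW) basis.  The
canonical internal representation everywhere else in the package is
**mg/kg dry weight**; conversions happen once, at ingest.

Dry- and wet-weight concentrations are related through the tissue moisture
fraction m (mass of water / total wet mass)::

    C_ww = C_dw * (1 - m)

so a dry-weight limit derived from a 1 mg/kg WW limit at 85 % hydration is
1 / 0.15 ≈ 6.7 mg/kg DW.
"""

from __future__ import annotations

from enum import Enum

__all__ = [
    "Unit",
    "Basis",
    "parse_unit",
    "parse_basis",
    "convert_unit",
    "dw_to_ww",
    "ww_to_dw",
    "UnitError",
]


class UnitError(ValueError):
    """Raised for unknown units/bases or invalid moisture fractions."""


class Unit(str, Enum):
    MG_PER_KG = "mg/kg"
    UG_PER_KG = "ug/kg"


class Basis(str, Enum):
    DRY = "DW"
    WET = "WW"
    UNSPECIFIED = "unspecified"


_UNIT_ALIASES = {
    "mg/kg": Unit.MG_PER_KG,
    "mg kg-1": Unit.MG_PER_KG,
    "ppm": Unit.MG_PER_KG,
    "ug/kg": Unit.UG_PER_KG,
    "µg/kg": Unit.UG_PER_KG,  # µ (micro sign)
    "μg/kg": Unit.UG_PER_KG,  # μ (greek mu)
    "ug kg-1": Unit.UG_PER_KG,
    "ng/g": Unit.UG_PER_KG,
    "ppb": Unit.UG_PER_KG,
}

_BASIS_ALIASES = {
    "dw": Basis.DRY,
    "dry": Basis.DRY,
    "dry-weight": Basis.DRY,
    "ww": Basis.WET,
    "wet": Basis.WET,
    "wet-weight": Basis.WET,
    "unspecified": Basis.UNSPECIFIED,
}

# mg/kg expressed in each unit
_PER_MG_KG = {Unit.MG_PER_KG: 1.0, Unit.UG_PER_KG: 1000.0}


def parse_unit(token: str | Unit) -> Unit:
    if isinstance(token, Unit):
        return token
    try:
        return _UNIT_ALIASES[str(token).strip().lower()]
    except KeyError:
        raise UnitError(f"unknown concentration unit: {token!r}") from None


def parse_basis(token: str | Basis) -> Basis:
    if isinstance(token, Basis):
        return token
    try:
        return _BASIS_ALIASES[str(token).strip().lower()]
    except KeyError:
        raise UnitError(f"unknown concentration basis: {token!r}") from None


def convert_unit(value: float, from_unit: str | Unit, to_unit: str | Unit) -> float:
    """Convert a concentration between mg/kg and µg/kg (exact factor 1000)."""
    fu, tu = parse_unit(from_unit), parse_unit(to_unit)
    if fu is tu:
        return value
    return value * _PER_MG_KG[tu] / _PER_MG_KG[fu]


def _check_moisture(moisture_fraction: float) -> float:
    m = float(moisture_fraction)
    if not 0.0 <= m < 1.0:
        raise UnitError(
            f"moisture fraction must be in [0, 1), got {moisture_fraction}"
        )
    return m


def dw_to_ww(conc_dw: float, moisture_fraction: float) -> float:
    """Dry-weight concentration -> wet-weight, given the moisture fraction."""
    m = _check_moisture(moisture_fraction)
    return conc_dw * (1.0 - m)


def ww_to_dw(conc_ww: float, moisture_fraction: float) -> float:
    """Wet-weight concentration -> dry-weight (inverse of :func:`dw_to_ww`)."""
    m = _check_moisture(moisture_fraction)
    return conc_ww / (1.0 - m)


def round_sig(x: float, sig: int = 3) -> float:
    """Round to ``sig`` significant figures (display helper; internal math
    is never rounded)."""
    if x == 0 or not (x == x):  # zero or nan
        return x
    from math import floor, log10

    return round(x, -int(floor(log10(abs(x)))) + (sig - 1))
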