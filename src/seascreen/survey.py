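"""Measurement records and delimited survey I/O.

A survey is a long-format table: one row per site x species x collection
date x analyte.  Values reported below the lower limit of quantitation
(LOQ) are left-censored; the literal token ``<LOQ`` in the value column
marks them, and the ``loq`` column carries the censoring threshold.

The canonical on-disk dialect is comma-separated with the header::

    site_code,site_name,species,collection_date,analyte_id,value,loq,unit,basis,latitude,moisture_fraction

``site_name``, ``latitude`` and ``moisture_fraction`` are optional and may
be blank or absent.  Dates are ISO-8601 with a MM/DD/YY fallback.
"""

from __future__ import annotations

import csv
import datetime as _dt
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from .units import Basis, Unit, UnitError, convert_unit, parse_basis, parse_unit, ww_to_dw

__all__ = [
    "Measurement",
    "SurveyTable",
    "SurveyParseError",
    "LowValueWarning",
    "read_survey",
    "write_survey",
    "canonicalize",
]

CENSORED_TOKEN = "<LOQ"

CANONICAL_COLUMNS = (
    "site_code",
    "site_name",
    "species",
    "collection_date",
    "analyte_id",
    "value",
    "loq",
    "unit",
    "basis",
    "latitude",
    "moisture_fraction",
)

MANDATORY_COLUMNS = (
    "site_code",
    "species",
    "collection_date",
    "analyte_id",
    "value",
    "loq",
    "unit",
    "basis",
)


class LowValueWarning(UserWarning):
    """A quantified value sits below its stated LOQ (accepted, not rejected)."""


class SurveyParseError(ValueError):
    """Aggregated row-numbered parse failures for one input file."""

    def __init__(self, errors: Sequence[tuple[int, str]]):
        self.errors = list(errors)
        lines = "; ".join(f"row {r}: {msg}" for r, msg in self.errors[:20])
        more = "" if len(self.errors) <= 20 else f" (+{len(self.errors) - 20} more)"
        super().__init__(f"{len(self.errors)} bad row(s): {lines}{more}")


@dataclass(frozen=True)
class Measurement:
    """One analyte concentration at one site/species/date.

    ``censored=True`` means the lab reported the value as below the LOQ:
    ``value`` is then ``None`` and ``loq`` must be present and positive.
    """

    site_code: str
    species: str
    collection_date: _dt.date
    analyte_id: str
    value: float | None
    loq: float | None
    unit: Unit
    basis: Basis
    censored: bool = False
    site_name: str = ""
    latitude: float | None = None
    moisture_fraction: float | None = None

    def __post_init__(self) -> None:
        if self.censored:
            if self.value is not None:
                raise ValueError(
                    f"{self.key()}: censored measurement must not carry a value"
                )
            if self.loq is None or self.loq <= 0:
                raise ValueError(
                    f"{self.key()}: censored measurement needs a positive LOQ"
                )
        else:
            if self.value is None or self.value < 0:
                raise ValueError(f"{self.key()}: value must be >= 0")
            if self.loq is not None and self.value < self.loq:
                warnings.warn(
                    f"{self.key()}: quantified value {self.value} below stated "
                    f"LOQ {self.loq}",
                    LowValueWarning,
                    stacklevel=2,
                )
        if self.moisture_fraction is not None and not (
            0.0 <= self.moisture_fraction <= 1.0
        ):
            raise ValueError(f"{self.key()}: moisture_fraction outside [0, 1]")

    def key(self) -> tuple[str, str, _dt.date, str]:
        return (self.site_code, self.species, self.collection_date, self.analyte_id)


@dataclass
class SurveyTable:
    """Ordered collection of measurements with unique row keys."""

    measurements: list[Measurement] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        seen: set[tuple] = set()
        for m in self.measurements:
            k = m.key()
            if k in seen:
                raise ValueError(f"duplicate measurement key {k}")
            seen.add(k)

    def __len__(self) -> int:
        return len(self.measurements)

    def __iter__(self) -> Iterator[Measurement]:
        return iter(self.measurements)

    def select(
        self,
        *,
        site_code: str | None = None,
        species: str | None = None,
        analyte_id: str | None = None,
    ) -> list[Measurement]:
        out = []
        for m in self.measurements:
            if site_code is not None and m.site_code != site_code:
                continue
            if species is not None and m.species != species:
                continue
            if analyte_id is not None and m.analyte_id != analyte_id:
                continue
            out.append(m)
        return out

    def samples(self) -> list[tuple[str, str, _dt.date]]:
        """Distinct (site, species, date) triples, in first-seen order."""
        seen: dict[tuple, None] = {}
        for m in self.measurements:
            seen.setdefault((m.site_code, m.species, m.collection_date))
        return list(seen)

    def to_frame(self):
        import pandas as pd

        rows = []
        for m in self.measurements:
            rows.append(
                {
                    "site_code": m.site_code,
                    "site_name": m.site_name,
                    "species": m.species,
                    "collection_date": m.collection_date,
                    "analyte_id": m.analyte_id,
                    "value": m.value,
                    "loq": m.loq,
                    "unit": m.unit.value,
                    "basis": m.basis.value,
                    "censored": m.censored,
                    "latitude": m.latitude,
                    "moisture_fraction": m.moisture_fraction,
                }
            )
        return pd.DataFrame(rows)


def _parse_date(token: str) -> _dt.date:
    token = token.strip()
    try:
        return _dt.date.fromisoformat(token)
    except ValueError:
        pass
    try:
        return _dt.datetime.strptime(token, "%m/%d/%y").date()
    except ValueError:
        raise ValueError(f"unparseable date {token!r} (ISO-8601 or MM/DD/YY)") from None


def _opt_float(token: str | None) -> float | None:
    if token is None or str(token).strip() == "":
        return None
    return float(token)


def _parse_row(row: dict[str, str]) -> Measurement:
    raw_value = (row.get("value") or "").strip()
    censored = raw_value.upper() in {CENSORED_TOKEN.upper(), "<LOD", "ND", "BDL"}
    value = None if censored else float(raw_value)
    return Measurement(
        site_code=row["site_code"].strip(),
        site_name=(row.get("site_name") or "").strip(),
        species=row["species"].strip(),
        collection_date=_parse_date(row["collection_date"]),
        analyte_id=row["analyte_id"].strip(),
        value=value,
        loq=_opt_float(row.get("loq")),
        unit=parse_unit(row["unit"]),
        basis=parse_basis(row["basis"]),
        censored=censored,
        latitude=_opt_float(row.get("latitude")),
        moisture_fraction=_opt_float(row.get("moisture_fraction")),
    )


def read_survey(
    path: str | Path,
    *,
    delimiter: str | None = None,
    column_map: dict[str, str] | None = None,
    provenance: str | None = None,
) -> SurveyTable:
    """Read a delimited long-format survey.

    Parameters
    ----------
    path
        Delimited text file; the first row is the header.
    delimiter
        Field separator.  ``None`` sniffs between comma and tab.
    column_map
        Optional mapping from header names in the file to canonical
        column names, for files with non-canonical headers.

    Raises
    ------
    SurveyParseError
        Listing every bad row by number.  A missing mandatory column is a
        hard failure naming the column.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if delimiter is None:
        first = text.splitlines()[0] if text.splitlines() else ""
        delimiter = "\t" if "\t" in first else ","
    reader = csv.DictReader(text.splitlines(), delimiter=delimiter)
    fields = reader.fieldnames or []
    if column_map:
        fields = [column_map.get(f, f) for f in fields]
        reader.fieldnames = fields
    missing = [c for c in MANDATORY_COLUMNS if c not in fields]
    if missing:
        raise SurveyParseError(
            [(0, f"missing mandatory column {c!r}") for c in missing]
        )

    measurements: list[Measurement] = []
    errors: list[tuple[int, str]] = []
    for lineno, row in enumerate(reader, start=2):
        try:
            measurements.append(_parse_row(row))
        except (ValueError, KeyError, UnitError) as exc:
            errors.append((lineno, str(exc)))
    if errors:
        raise SurveyParseError(errors)
    return SurveyTable(
        measurements=measurements,
        provenance=provenance if provenance is not None else str(path),
    )


def write_survey(table: SurveyTable, path: str | Path) -> None:
    """Write in the canonical comma-separated dialect (read/write fixed point)."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(CANONICAL_COLUMNS)
        for m in table.measurements:
            w.writerow(
                [
                    m.site_code,
                    m.site_name,
                    m.species,
                    m.collection_date.isoformat(),
                    m.analyte_id,
                    CENSORED_TOKEN if m.censored else repr(m.value),
                    "" if m.loq is None else repr(m.loq),
                    m.unit.value,
                    m.basis.value,
                    "" if m.latitude is None else repr(m.latitude),
                    "" if m.moisture_fraction is None else repr(m.moisture_fraction),
                ]
            )


def canonicalize(
    table: SurveyTable,
    *,
    species_moisture: dict[str, float] | None = None,
) -> SurveyTable:
    """Convert every measurement to the canonical mg/kg dry-weight form.

    Unit conversion is exact (factor 1000).  Wet-basis rows need moisture
    information: per-row ``moisture_fraction`` first, then the per-species
    default in ``species_moisture``; rows with neither fail loudly (no
    imputation).
    """
    species_moisture = species_moisture or {}
    out: list[Measurement] = []
    errors: list[tuple[int, str]] = []
    for i, m in enumerate(table.measurements, start=1):
        value, loq = m.value, m.loq
        if m.unit is not Unit.MG_PER_KG:
            if value is not None:
                value = convert_unit(value, m.unit, Unit.MG_PER_KG)
            if loq is not None:
                loq = convert_unit(loq, m.unit, Unit.MG_PER_KG)
        basis = m.basis
        if basis is Basis.WET:
            moisture = m.moisture_fraction
            if moisture is None:
                moisture = species_moisture.get(m.species)
            if moisture is None:
                errors.append(
                    (i, f"{m.key()}: wet-basis row without moisture information")
                )
                continue
            if value is not None:
                value = ww_to_dw(value, moisture)
            if loq is not None:
                loq = ww_to_dw(loq, moisture)
            basis = Basis.DRY
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", LowValueWarning)
            out.append(
                replace(m, value=value, loq=loq, unit=Unit.MG_PER_KG, basis=basis)
            )
    if errors:
        raise SurveyParseError(errors)
    return SurveyTable(measurements=out, provenance=table.provenance)
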