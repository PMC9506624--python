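"""Registries: analyte definitions, toxicity constants, exposure parameters,
international limits, and common-food portion data.

Toxicity constants are data, not code.  The shipped fixture registry
(``data/toxrefs.yaml``) freezes era-appropriate oral reference doses (RfD,
mg/kg-day) and cancer slope factors (CSF, (mg/kg-day)^-1) back-derived from
the screening levels they must reproduce at the default exposure
parameters; each entry names the IRIS chemical it corresponds to and, for
speciated metals, the conservative surrogate used (methyl Hg for total Hg,
inorganic As for total As, Cr(VI) for total Cr, V pentoxide for V).
``lint_toxrefs`` recomputes every screening level from the registry and
compares it with the expected printed value stored alongside — that check
is the fixture's definition of correctness.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import yaml

from .units import Basis, Unit, parse_basis, parse_unit, ww_to_dw

__all__ = [
    "AnalyteDef",
    "GroupDef",
    "ToxRef",
    "ExposureParams",
    "RegulatoryLimit",
    "FoodItem",
    "ResolvedLimit",
    "RegistryError",
    "load_analytes",
    "load_toxrefs",
    "load_limits",
    "load_foods",
    "default_analytes",
    "default_groups",
    "default_toxrefs",
    "default_limits",
    "default_foods",
    "lowest_limit",
    "lint_toxrefs",
]

ANALYTE_CLASSES = frozenset(
    {"metal", "PCB", "PBDE", "PCDD/F", "PAH", "organochlorine pesticide"}
)


class RegistryError(ValueError):
    pass


@dataclass(frozen=True)
class AnalyteDef:
    analyte_id: str
    display_name: str
    analyte_class: str
    groups: frozenset[str] = frozenset()
    tef: float | None = None

    def __post_init__(self):
        if self.analyte_class not in ANALYTE_CLASSES:
            raise RegistryError(
                f"{self.analyte_id}: unknown analyte class {self.analyte_class!r}"
            )
        if self.tef is not None and not 0.0 < self.tef <= 1.0:
            raise RegistryError(f"{self.analyte_id}: TEF must be in (0, 1]")


@dataclass(frozen=True)
class GroupDef:
    group_label: str
    member_analytes: tuple[str, ...]
    mode: str  # plain_sum | tef_weighted_sum

    def __post_init__(self):
        if not self.member_analytes:
            raise RegistryError(f"group {self.group_label}: no members")
        if self.mode not in {"plain_sum", "tef_weighted_sum"}:
            raise RegistryError(f"group {self.group_label}: unknown mode {self.mode}")


@dataclass(frozen=True)
class ToxRef:
    """Per-analyte oral toxicity constants.

    rfd : mg per kg body weight per day (noncancer); csf : (mg/kg-day)^-1.
    At least one must be present.
    """

    analyte_id: str
    rfd: float | None = None
    csf: float | None = None
    surrogate_note: str = ""
    iris_chemical: str = ""

    def __post_init__(self):
        if self.rfd is None and self.csf is None:
            raise RegistryError(f"{self.analyte_id}: need at least one of rfd, csf")
        for name, v in (("rfd", self.rfd), ("csf", self.csf)):
            if v is not None and v < 0:
                raise RegistryError(f"{self.analyte_id}: {name} must be nonnegative")


@dataclass(frozen=True)
class ExposureParams:
    """Adult exposure assumptions behind every screening level.

    bw : body weight, kg (default 80).
    cr : seaweed consumption rate, g dry weight per day (default 5, a
         typical meal-sized portion).
    arl : acceptable excess lifetime cancer risk (default 1e-6).
    """

    bw: float = 80.0
    cr: float = 5.0
    arl: float = 1e-6

    def __post_init__(self):
        if not (self.bw > 0 and self.cr > 0 and self.arl > 0):
            raise RegistryError("exposure parameters must be strictly positive")


@dataclass(frozen=True)
class RegulatoryLimit:
    analyte_id: str
    jurisdiction: str
    limit_value: float
    unit: Unit
    basis: Basis
    applies_to: str = ""

    def __post_init__(self):
        if self.limit_value <= 0:
            raise RegistryError(
                f"{self.analyte_id}/{self.jurisdiction}: limit must be > 0"
            )


@dataclass(frozen=True)
class ResolvedLimit:
    """A regulatory limit expressed on the requested basis (mg/kg)."""

    limit: RegulatoryLimit
    value: float
    basis: Basis


@dataclass(frozen=True)
class FoodItem:
    food_name: str
    contaminant: str
    conc: float  # mg/kg wet weight
    portion_mass: float  # g wet weight per portion
    citation: str = ""

    def __post_init__(self):
        if self.portion_mass <= 0:
            raise RegistryError(f"{self.food_name}: portion_mass must be > 0")
        if self.conc < 0:
            raise RegistryError(f"{self.food_name}: concentration must be >= 0")


# ---------------------------------------------------------------------------
# loading

def _load_yaml(path: str | Path):
    with open(path, "r", encoding="utf-8") as fh:
        return yaml.safe_load(fh)


def _unique_key(entries: Iterable, keyfunc, what: str) -> dict:
    out = {}
    for e in entries:
        k = keyfunc(e)
        if k in out:
            raise RegistryError(f"duplicate {what} entry: {k}")
        out[k] = e
    return out


def load_analytes(path: str | Path) -> tuple[dict[str, AnalyteDef], dict[str, GroupDef]]:
    """Load the analyte registry (definitions + group memberships).

    Group membership is declared on the group side (``groups:`` section);
    the per-analyte ``groups`` field is derived from it.  TEF-weighted
    groups require a TEF on every member.
    """
    doc = _load_yaml(path)
    groups = {}
    for g in doc.get("groups", []):
        gd = GroupDef(
            group_label=g["group_label"],
            member_analytes=tuple(g["members"]),
            mode=g.get("mode", "plain_sum"),
        )
        if gd.group_label in groups:
            raise RegistryError(f"duplicate group {gd.group_label}")
        groups[gd.group_label] = gd

    membership: dict[str, set[str]] = {}
    for gd in groups.values():
        for a in gd.member_analytes:
            membership.setdefault(a, set()).add(gd.group_label)

    analytes: dict[str, AnalyteDef] = {}
    for a in doc.get("analytes", []):
        ad = AnalyteDef(
            analyte_id=a["analyte_id"],
            display_name=a.get("display_name", a["analyte_id"]),
            analyte_class=a["analyte_class"],
            groups=frozenset(membership.get(a["analyte_id"], ())),
            tef=a.get("tef"),
        )
        if ad.analyte_id in analytes:
            raise RegistryError(f"duplicate analyte {ad.analyte_id}")
        analytes[ad.analyte_id] = ad

    for gd in groups.values():
        for a in gd.member_analytes:
            if a not in analytes:
                raise RegistryError(
                    f"group {gd.group_label} references undeclared analyte {a}"
                )
            if gd.mode == "tef_weighted_sum" and analytes[a].tef is None:
                raise RegistryError(
                    f"group {gd.group_label}: member {a} lacks a TEF"
                )
    return analytes, groups


def load_toxrefs(path: str | Path) -> dict[str, ToxRef]:
    doc = _load_yaml(path)
    refs = [
        ToxRef(
            analyte_id=e["analyte_id"],
            rfd=e.get("rfd"),
            csf=e.get("csf"),
            surrogate_note=e.get("surrogate_note") or "",
            iris_chemical=e.get("iris_chemical") or "",
        )
        for e in doc["toxrefs"]
    ]
    return _unique_key(refs, lambda r: r.analyte_id, "toxref")


def _load_expected_sls(path: str | Path) -> dict[str, dict]:
    """Printed screening levels stored next to each toxref, for linting."""
    doc = _load_yaml(path)
    out = {}
    for e in doc["toxrefs"]:
        exp = {}
        for kind in ("expected_sl_rfd", "expected_sl_csf"):
            if e.get(kind) is not None:
                raw = e[kind]["value"]
                exp[kind] = {
                    "value": float(raw),
                    "printed": str(raw),  # as written, for precision detection
                    "unit": parse_unit(e[kind]["unit"]),
                }
        if exp:
            out[e["analyte_id"]] = exp
    return out


def load_limits(path: str | Path) -> dict[str, list[RegulatoryLimit]]:
    doc = _load_yaml(path)
    out: dict[str, list[RegulatoryLimit]] = {}
    seen = set()
    for e in doc["limits"]:
        lim = RegulatoryLimit(
            analyte_id=e["analyte_id"],
            jurisdiction=e["jurisdiction"],
            limit_value=float(e["limit_value"]),
            unit=parse_unit(e["unit"]),
            basis=parse_basis(e["basis"]),
            applies_to=e.get("applies_to") or "",
        )
        k = (lim.analyte_id, lim.jurisdiction, lim.limit_value)
        if k in seen:
            raise RegistryError(f"duplicate limit entry: {k}")
        seen.add(k)
        out.setdefault(lim.analyte_id, []).append(lim)
    return out


def load_foods(path: str | Path) -> list[FoodItem]:
    doc = _load_yaml(path)
    items = [
        FoodItem(
            food_name=e["food_name"],
            contaminant=e["contaminant"],
            conc=float(e["conc"]),
            portion_mass=float(e["portion_mass"]),
            citation=e.get("citation") or "",
        )
        for e in doc["foods"]
    ]
    _unique_key(items, lambda f: (f.food_name, f.contaminant), "food")
    return items


def _data_path(name: str) -> Path:
    return Path(str(resources.files("seascreen").joinpath("data", name)))


def default_analytes() -> tuple[dict[str, AnalyteDef], dict[str, GroupDef]]:
    return load_analytes(_data_path("analytes.yaml"))


def default_groups() -> dict[str, GroupDef]:
    return default_analytes()[1]


def default_toxrefs() -> dict[str, ToxRef]:
    return load_toxrefs(_data_path("toxrefs.yaml"))


def default_limits() -> dict[str, list[RegulatoryLimit]]:
    return load_limits(_data_path("limits.yaml"))


def default_foods() -> list[FoodItem]:
    return load_foods(_data_path("foods.yaml"))


# ---------------------------------------------------------------------------
# operations

def lowest_limit(
    limits: Mapping[str, list[RegulatoryLimit]],
    analyte_id: str,
    basis: Basis | str = Basis.DRY,
    *,
    moisture_fraction: float | None = None,
    log: list[str] | None = None,
) -> ResolvedLimit | None:
    """Most conservative international limit for an analyte, on ``basis``.

    Limits stated on a wet basis are converted to the requested dry basis
    with the supplied moisture fraction; without moisture information they
    are excluded (with a note appended to ``log``), as are limits whose
    basis is unspecified.  Ties break alphabetically by jurisdiction.
    """
    basis = parse_basis(basis)
    if basis is not Basis.DRY:
        raise RegistryError("limits are compared on the dry-weight basis")
    candidates: list[tuple[float, str, RegulatoryLimit]] = []
    for lim in limits.get(analyte_id, []):
        value_mg = lim.limit_value if lim.unit is Unit.MG_PER_KG else lim.limit_value / 1000.0
        if lim.basis is Basis.DRY:
            candidates.append((value_mg, lim.jurisdiction, lim))
        elif lim.basis is Basis.WET:
            if moisture_fraction is None:
                if log is not None:
                    log.append(
                        f"{analyte_id}: wet-basis limit ({lim.jurisdiction}) "
                        "excluded — no moisture information"
                    )
                continue
            candidates.append(
                (ww_to_dw(value_mg, moisture_fraction), lim.jurisdiction, lim)
            )
        else:
            if log is not None:
                log.append(
                    f"{analyte_id}: limit with unspecified basis "
                    f"({lim.jurisdiction}) excluded"
                )
    if not candidates:
        return None
    value, _, lim = min(candidates, key=lambda c: (c[0], c[1]))
    return ResolvedLimit(limit=lim, value=value, basis=Basis.DRY)


def lint_toxrefs(
    toxrefs_path: str | Path | None = None,
    params: ExposureParams | None = None,
) -> list[dict]:
    """Recompute screening levels from the registry and compare with the
    expected values stored next to each entry.

    Returns one row per expected value with the computed level, the expected
    level, and whether they agree to the expected value's printed precision.
    """
    from .screening import sl_csf, sl_rfd
    from .units import convert_unit, round_sig

    path = toxrefs_path or _data_path("toxrefs.yaml")
    params = params or ExposureParams()
    toxrefs = load_toxrefs(path)
    expected = _load_expected_sls(path)
    rows = []
    for analyte_id, exp in expected.items():
        ref = toxrefs[analyte_id]
        for kind, e in exp.items():
            computed_mg = (
                sl_rfd(ref, params) if kind == "expected_sl_rfd" else sl_csf(ref, params)
            )
            computed = convert_unit(computed_mg, Unit.MG_PER_KG, e["unit"])
            printed = e["value"]
            # agreement to the printed number of significant figures
            digits = e["printed"].replace(".", "").replace("-", "").lstrip("0")
            sig = len(digits.rstrip("0")) or len(digits)
            ok = round_sig(computed, max(sig, 1)) == round_sig(printed, max(sig, 1))
            rows.append(
                {
                    "analyte_id": analyte_id,
                    "kind": kind.removeprefix("expected_"),
                    "computed": computed,
                    "expected": printed,
                    "unit": e["unit"].value,
                    "ok": ok,
                }
            )
    return rows
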