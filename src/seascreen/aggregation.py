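"""Congener-group sums and TEF-weighted toxic equivalents.

Substitution for censored congeners happens at the individual-congener
level *before* summation, so a group sum under the half-LOQ policy is
exactly the midpoint of the zero and full-LOQ sums.  TEF-weighted sums
(toxic equivalents, TEQ) weight each congener by its toxic equivalency
factor relative to 2,3,7,8-TCDD and are expressed in TEQ units of that
reference congener.

Summation order is fixed ascending by analyte_id so floating-point output
is reproducible under any input permutation.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import replace
from typing import Mapping, Sequence

from .censoring import SubstitutionPolicy, substitute
from .registries import AnalyteDef, GroupDef
from .survey import Measurement, SurveyTable

__all__ = [
    "GroupMembershipError",
    "group_sum",
    "sum_bounds",
    "aggregate_survey",
    "TotalPCBEstimator",
]

AGGREGATE_PROVENANCE = "aggregated"


class GroupMembershipError(ValueError):
    pass


def _members_in_order(
    sample: Sequence[Measurement], group: GroupDef
) -> list[Measurement]:
    by_id = {m.analyte_id: m for m in sample}
    missing = [a for a in group.member_analytes if a not in by_id]
    if missing:
        raise GroupMembershipError(
            f"group {group.group_label}: absent congeners {sorted(missing)}"
        )
    return [by_id[a] for a in sorted(group.member_analytes)]


def group_sum(
    sample: Sequence[Measurement],
    group: GroupDef,
    policy: SubstitutionPolicy | str,
    analytes: Mapping[str, AnalyteDef] | None = None,
) -> float:
    """Group sum for one sample (all measurements share site/species/date).

    plain_sum: sum of substituted member values.  tef_weighted_sum: sum of
    substituted value x TEF (requires ``analytes`` for the TEF lookup).
    Missing members are an error, never a silent zero.
    """
    members = _members_in_order(sample, group)
    values = substitute(members, policy, same_analyte=False)
    if group.mode == "plain_sum":
        return float(values.sum())
    if analytes is None:
        raise GroupMembershipError(
            f"group {group.group_label}: TEF-weighted sum needs the analyte registry"
        )
    total = 0.0
    for m, v in zip(members, values):
        adef = analytes.get(m.analyte_id)
        if adef is None or adef.tef is None:
            raise GroupMembershipError(
                f"group {group.group_label}: member {m.analyte_id} lacks a TEF"
            )
        total += v * adef.tef
    return total


def sum_bounds(
    sample: Sequence[Measurement],
    group: GroupDef,
    analytes: Mapping[str, AnalyteDef] | None = None,
) -> tuple[float, float, float]:
    """(sum under zero, half-LOQ, full-LOQ) — nondecreasing, with the
    half-LOQ sum the exact midpoint of the other two."""
    return tuple(
        group_sum(sample, group, p, analytes)
        for p in (
            SubstitutionPolicy.ZERO,
            SubstitutionPolicy.HALF_LOQ,
            SubstitutionPolicy.FULL_LOQ,
        )
    )


def aggregate_survey(
    survey: SurveyTable,
    groups: Mapping[str, GroupDef],
    policy: SubstitutionPolicy | str = SubstitutionPolicy.HALF_LOQ,
    analytes: Mapping[str, AnalyteDef] | None = None,
    *,
    skip_incomplete: bool = True,
) -> SurveyTable:
    """Append one aggregated row per sample x group, under the given policy.

    Aggregated rows carry the group label as a synthetic analyte_id (e.g.
    ``SUM_PCB40``) and ``site_name`` provenance tagging.  Samples missing
    any member analyte are skipped when ``skip_incomplete`` (a sample that
    was never analysed for that class), otherwise raise.
    """
    new_rows: list[Measurement] = []
    for site, species, date in survey.samples():
        sample = [
            m
            for m in survey.measurements
            if (m.site_code, m.species, m.collection_date) == (site, species, date)
        ]
        template = sample[0]
        for group in groups.values():
            try:
                total = group_sum(sample, group, policy, analytes)
            except GroupMembershipError:
                if skip_incomplete:
                    continue
                raise
            members = _members_in_order(sample, group)
            new_rows.append(
                replace(
                    template,
                    analyte_id=group.group_label,
                    value=total,
                    loq=None,
                    censored=False,
                    unit=members[0].unit,
                    basis=members[0].basis,
                )
            )
    return SurveyTable(
        measurements=list(survey.measurements) + new_rows,
        provenance=(survey.provenance + f" + {AGGREGATE_PROVENANCE}").strip(),
    )


class TotalPCBEstimator:
    """Optional linear estimator of total PCBs from a measured subset sum,
    ``total ~= a * subset_sum + b``.

    No default coefficients are shipped; they must be supplied by the user
    (they are calibration constants of a particular monitoring program).
    """

    def __init__(self, a: float, b: float = 0.0):
        self.a = float(a)
        self.b = float(b)

    def __call__(self, subset_sum: float) -> float:
        return self.a * subset_sum + self.b
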