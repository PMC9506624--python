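import datetime as dt

import pytest

import seascreen as ss
from seascreen.registries import ExposureParams, RegulatoryLimit, ToxRef
from seascreen.screening import (
    NoScreeningLevel,
    evaluate,
    pct_of_reference,
    screening_levels,
    sl_csf,
    sl_rfd,
)
from seascreen.survey import SurveyTable
from seascreen.units import Basis, Unit

from .conftest import make_measurement

P = ExposureParams()  # bw 80, cr 5, arl 1e-6


@pytest.mark.parametrize(
    "rfd,expected",
    [(1.0e-3, 16.0), (1.0e-4, 1.6), (3.0e-4, 4.8), (0.0, 0.0)],
)
def test_sl_rfd(rfd, expected):
    ref = ToxRef(analyte_id="X", rfd=rfd, csf=1.0)
    assert sl_rfd(ref, P) == pytest.approx(expected)


@pytest.mark.parametrize(
    "csf,expected_mg",
    [(2.0, 0.008), (1.0, 0.016), (1.5, 0.016 / 1.5)],
)
def test_sl_csf(csf, expected_mg):
    ref = ToxRef(analyte_id="X", csf=csf)
    assert sl_csf(ref, P) == pytest.approx(expected_mg)


def test_sl_scales_with_arl():
    ref = ToxRef(analyte_id="X", csf=2.0)
    tiny = ExposureParams(arl=1e-9)
    assert sl_csf(ref, tiny) == pytest.approx(sl_csf(ref, P) * 1e-3)


def test_missing_constant_is_a_marker_not_zero():
    with pytest.raises(NoScreeningLevel):
        sl_rfd(ToxRef(analyte_id="X", csf=1.0), P)
    with pytest.raises(NoScreeningLevel):
        sl_csf(ToxRef(analyte_id="X", rfd=1.0), P)


@pytest.mark.parametrize("factor", [2.0, 0.5, 10.0])
def test_doubling_cr_halves_every_level(factor):
    ref = ToxRef(analyte_id="X", rfd=3e-4, csf=1.5)
    scaled = ExposureParams(cr=P.cr * factor)
    assert sl_rfd(ref, scaled) == pytest.approx(sl_rfd(ref, P) / factor)
    assert sl_csf(ref, scaled) == pytest.approx(sl_csf(ref, P) / factor)


def test_evaluate_international_exceedance(registries, levels):
    # kelp Cd minimum against the lowest international limit (0.2 DW)
    survey = SurveyTable([make_measurement(analyte_id="Cd", value=2.48)])
    records = evaluate(survey, levels, registries["limits"], "half")
    intl = [r for r in records if r.reference_kind == "international"]
    assert len(intl) == 1
    assert intl[0].jurisdiction == "Australia/New Zealand"
    assert intl[0].exceeds and intl[0].ratio == pytest.approx(12.4)
    # ... but not the noncancer screening level of 16 mg/kg
    rfd = [r for r in records if r.reference_kind == "sl_rfd"]
    assert not rfd[0].exceeds


def test_exactly_at_reference_does_not_exceed(levels):
    survey = SurveyTable([make_measurement(analyte_id="Cd", value=16.0)])
    records = evaluate(survey, levels, {}, "half")
    rfd = [r for r in records if r.reference_kind == "sl_rfd"]
    assert rfd[0].ratio == pytest.approx(1.0) and not rfd[0].exceeds


def test_wet_basis_limit_conversion(levels):
    # kelp Cd maximum vs a 3 mg/kg WW supplements limit at 85% moisture:
    # 7.91 DW -> 1.19 WW, under the limit (converted: 20 mg/kg DW)
    ec_only = {
        "Cd": [
            RegulatoryLimit(
                "Cd", "European Commission", 3.0, Unit.MG_PER_KG, Basis.WET
            )
        ]
    }
    survey = SurveyTable(
        [make_measurement(analyte_id="Cd", value=7.91, species="N_luetkeana")]
    )
    records = evaluate(
        survey, {}, ec_only, "half", species_moisture={"N_luetkeana": 0.85}
    )
    intl = [r for r in records if r.reference_kind == "international"]
    assert len(intl) == 1 and not intl[0].exceeds
    assert intl[0].reference_value == pytest.approx(20.0)


def test_no_reference_yields_informational_record(levels):
    survey = SurveyTable([make_measurement(analyte_id="Fe", value=100.0)])
    (rec,) = evaluate(survey, levels, {}, "half")
    assert rec.reference_kind == "none" and not rec.exceeds


def test_censored_measurements_use_policy_value(levels):
    survey = SurveyTable(
        [make_measurement(analyte_id="Cd", censored=True, loq=40.0)]
    )
    for policy, conc in [("zero", 0.0), ("half", 20.0), ("full", 40.0)]:
        recs = evaluate(survey, levels, {}, policy)
        rfd = [r for r in recs if r.reference_kind == "sl_rfd"][0]
        assert rfd.conc == pytest.approx(conc)
        assert rfd.exceeds == (conc > 16.0)


def test_evaluate_policy_monotone(synthetic_survey, registries, levels):
    """Moving zero -> half -> full substitution can only add exceedances."""
    survey, _ = synthetic_survey
    flagged = {}
    for policy in ("zero", "half", "full"):
        recs = evaluate(survey, levels, registries["limits"], policy)
        flagged[policy] = {
            (r.site_code, r.species, r.analyte_id, r.reference_kind)
            for r in recs
            if r.exceeds
        }
    assert flagged["zero"] <= flagged["half"] <= flagged["full"]


def test_pct_of_reference():
    assert pct_of_reference(151, 220) == pytest.approx(68.6363, abs=1e-3)
    assert round(pct_of_reference(151, 220)) == 69
    assert pct_of_reference(0, 5) == 0.0
    assert pct_of_reference(82.6, 640000) == pytest.approx(0.0129, abs=1e-4)
    with pytest.raises(ValueError):
        pct_of_reference(1.0, 0.0)


def test_surrogates_propagate(registries, levels):
    assert "methyl" in levels["Hg"].surrogate_note
    assert "inorganic As" in levels["tAs"].surrogate_note
    survey = SurveyTable([make_measurement(analyte_id="tAs", value=26.8)])
    recs = evaluate(survey, levels, {}, "half")
    assert all("inorganic" in r.surrogate_note for r in recs if r.reference_kind.startswith("sl"))


def test_pb_has_only_international_references(registries, levels):
    # no oral RfD/CSF exists for Pb: screening is by international limit only
    assert "Pb" not in levels
    survey = SurveyTable([make_measurement(analyte_id="Pb", value=13.2)])
    recs = evaluate(survey, levels, registries["limits"], "half")
    kinds = {r.reference_kind for r in recs}
    assert kinds == {"international"}
    assert recs[0].exceeds  # 13.2 vs the 1 mg/kg DW lowest limit
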