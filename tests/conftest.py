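import datetime as dt

import pytest
from hypothesis import settings

import seascreen as ss

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from seascreen.survey import Measurement, SurveyTable
from seascreen.units import Basis, Unit


def make_measurement(
    analyte_id="X",
    value=1.0,
    loq=None,
    censored=False,
    site_code="S01",
    species="F_distichus",
    date=dt.date(2015, 7, 1),
    unit=Unit.MG_PER_KG,
    basis=Basis.DRY,
    **kw,
):
    """Terse Measurement factory for tests."""
    return Measurement(
        site_code=site_code,
        species=species,
        collection_date=date,
        analyte_id=analyte_id,
        value=None if censored else value,
        loq=loq,
        unit=unit,
        basis=basis,
        censored=censored,
        **kw,
    )


@pytest.fixture(scope="session")
def registries():
    analytes, groups = ss.default_analytes()
    return {
        "analytes": analytes,
        "groups": groups,
        "toxrefs": ss.default_toxrefs(),
        "limits": ss.default_limits(),
        "foods": ss.default_foods(),
    }


@pytest.fixture(scope="session")
def levels(registries):
    return ss.screening_levels(registries["toxrefs"], ss.ExposureParams())


@pytest.fixture(scope="session")
def synthetic_survey():
    """One default-condition synthetic survey with its truth manifest."""
    config = ss.salishlike_config(seed=20150601)
    return ss.generate(config)


def in_paper_survey():
    """Mini-survey of concentrations printed in the motivating field study:
    the maxima that drive its site advisories, in their reported units."""
    rows = [
        # site, species, analyte, value, loq, unit
        ("RB", "F_distichus", "BaP", 64.6, 1.60, Unit.UG_PER_KG),
        ("RB", "F_distichus", "SUM_PCB40", 21.2, None, Unit.UG_PER_KG),
        ("RB", "F_distichus", "Cd", 2.52, 0.1, Unit.MG_PER_KG),
        ("RB", "F_distichus", "Hg", None, 0.1, Unit.MG_PER_KG),  # censored
        ("PO", "F_spiralis", "BaP", 20.8, 1.50, Unit.UG_PER_KG),
        ("PO", "F_spiralis", "SUM_PCB40", 14.2, None, Unit.UG_PER_KG),
        ("PO", "F_spiralis", "Pb", 13.4, 0.1, Unit.MG_PER_KG),
        ("PH", "F_distichus", "Pb", 13.2, 0.1, Unit.MG_PER_KG),
    ]
    ms = [
        make_measurement(
            analyte_id=a,
            value=v,
            loq=loq,
            censored=v is None,
            site_code=s,
            species=sp,
            unit=u,
        )
        for s, sp, a, v, loq, u in rows
    ]
    return SurveyTable(measurements=ms, provenance="printed field maxima")


@pytest.fixture()
def paper_survey():
    return ss.canonicalize(in_paper_survey())
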