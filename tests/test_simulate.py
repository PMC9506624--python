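import math

import numpy as np
import pytest

import seascreen as ss
from seascreen.aggregation import group_sum
from seascreen.censoring import summarize
from seascreen.simulate import (
    FUCOID_A,
    KELP,
    AnalyteModel,
    GeneratorConfig,
    generate,
    recover,
    salishlike_config,
)
from seascreen.stats import paired_t


def tiny_config(**kw):
    defaults = dict(
        n_sites=10,
        species_sites={FUCOID_A: tuple(range(10))},
        analytes=(AnalyteModel("Cd", math.log(2.0), 0.3, 0.1),),
        seed=1,
    )
    defaults.update(kw)
    return GeneratorConfig(**defaults)


def test_determinism():
    cfg = salishlike_config(seed=77)
    s1, m1 = generate(cfg)
    s2, m2 = generate(cfg)
    assert s1.measurements == s2.measurements
    assert m1.true_values == m2.true_values
    assert m1.outlier_sites == m2.outlier_sites


def test_different_seed_differs():
    s1, _ = generate(tiny_config(seed=1))
    s2, _ = generate(tiny_config(seed=2))
    assert s1.measurements != s2.measurements


def test_degenerate_zero_spread():
    cfg = tiny_config(analytes=(AnalyteModel("Cd", math.log(2.0), 0.0, 0.1),))
    survey, manifest = generate(cfg)
    assert all(m.value == pytest.approx(2.0) for m in survey)
    assert all(v == pytest.approx(2.0) for v in manifest.true_values.values())


def test_species_effect_multiplies_median():
    cfg = tiny_config(
        species_sites={FUCOID_A: tuple(range(10)), KELP: tuple(range(10))},
        analytes=(
            AnalyteModel("Cd", math.log(2.0), 0.0, 0.1, species_effect={KELP: 3.0}),
        ),
    )
    survey, _ = generate(cfg)
    kelp = [m.value for m in survey.select(species=KELP)]
    fuc = [m.value for m in survey.select(species=FUCOID_A)]
    assert np.allclose(np.array(kelp), 3.0 * np.array(fuc))


def test_loq_above_distribution_censors_everything():
    cfg = tiny_config(analytes=(AnalyteModel("Hg", math.log(0.01), 0.2, 10.0),))
    survey, _ = generate(cfg)
    assert all(m.censored for m in survey)
    s = summarize(survey.measurements, "half")
    assert s.mean == pytest.approx(5.0)  # loq/2


def test_censoring_is_deterministic_at_loq():
    survey, manifest = generate(salishlike_config(seed=4))
    for m in survey:
        truth = manifest.true_values[(m.site_code, m.species, m.analyte_id)]
        assert m.censored == (truth < m.loq)
        if not m.censored:
            assert m.value == truth


def test_species_ratio_recovery():
    """A planted 2.84x kelp:fucoid ratio is recovered by the paired
    comparison within +/-15% at the default spread."""
    shared = tuple(range(40))
    mu = math.log(26.8) - 0.1836**2 / 2
    cfg = GeneratorConfig(
        n_sites=40,
        species_sites={FUCOID_A: shared, KELP: shared},
        analytes=(
            AnalyteModel("tAs", mu, 0.1836, 0.1, species_effect={KELP: 2.84}),
        ),
        seed=20150601,
    )
    survey, _ = generate(cfg)
    by_site = {}
    for m in survey:
        by_site.setdefault(m.site_code, {})[m.species] = m.value
    a = [v[FUCOID_A] for v in by_site.values()]
    b = [v[KELP] for v in by_site.values()]
    cmp_ = paired_t(a, b, alpha=0.017)
    assert cmp_.pct_higher == pytest.approx(184.0, rel=0.15)
    assert cmp_.significant


def test_truth_sums_bracketed_by_policy_sums(registries):
    """With nonnegative truth censored exactly at the LOQ, every true group
    sum lies within [zero-substituted, LOQ-substituted] sums."""
    survey, manifest = generate(salishlike_config(seed=6))
    group = registries["groups"]["SUM_PCB40"]
    for site, species, date in survey.samples():
        sample = [
            m
            for m in survey
            if (m.site_code, m.species, m.collection_date) == (site, species, date)
            and m.analyte_id.startswith("PCB")
        ]
        if len(sample) != 40:
            continue
        truth_sum = sum(
            manifest.true_values[(site, species, m.analyte_id)] for m in sample
        )
        lo = group_sum(sample, group, "zero")
        hi = group_sum(sample, group, "full")
        assert lo - 1e-12 <= truth_sum <= hi + 1e-12


def test_advisory_exact_without_censoring(levels):
    """With censoring disabled the advisory rates invert the truth exactly."""
    cfg = tiny_config(
        analytes=(AnalyteModel("Cd", math.log(30.0), 0.5, 0.0),), seed=3
    )
    survey, manifest = generate(cfg)
    rows = ss.build_advisory(survey, levels, {}, policy="half")
    sl = levels["Cd"].sl_rfd
    for row in rows:
        truth = manifest.true_values[(row.site_code, FUCOID_A, "Cd")]
        assert row.per_analyte_rate["Cd"] == pytest.approx(5.0 * sl / truth, rel=1e-12)


def test_recover_no_outliers(levels):
    survey, manifest = generate(tiny_config(n_outlier_sites=0))
    report = recover(survey, manifest, levels)
    assert report.outlier_recall is None
    assert report.exceedance_specificity["HALF_LOQ"] is not None


def test_recover_mismatch_fails(levels):
    survey, _ = generate(tiny_config(seed=1))
    _, manifest = generate(tiny_config(seed=2, analytes=(
        AnalyteModel("Zn", math.log(2.0), 0.3, 0.1),
    )))
    with pytest.raises(ValueError, match="mismatch"):
        recover(survey, manifest, levels)


def test_config_validation():
    with pytest.raises(ValueError):
        tiny_config(n_outlier_sites=10)
    with pytest.raises(ValueError):
        GeneratorConfig(
            n_sites=5,
            species_sites={FUCOID_A: (7,)},
            analytes=(AnalyteModel("Cd", 0.0, 0.1, 0.1),),
        )


def test_salishlike_summaries_near_targets():
    """Default conditions land near the field survey's species summaries."""
    survey, _ = generate(salishlike_config(seed=0))
    tas = summarize(survey.select(species=FUCOID_A, analyte_id="tAs"), "half")
    assert tas.n == 38
    assert tas.mean == pytest.approx(26.8, rel=0.15)
    kelp_tas = summarize(survey.select(species=KELP, analyte_id="tAs"), "half")
    assert kelp_tas.mean == pytest.approx(72.5, rel=0.2)
    cd = summarize(survey.select(species=FUCOID_A, analyte_id="Cd"), "half")
    assert cd.mean == pytest.approx(2.52, rel=0.25)
    hg = summarize(survey.select(species=FUCOID_A, analyte_id="Hg"), "half")
    assert 5 <= hg.pct_above_loq <= 40  # mostly censored, as observed
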