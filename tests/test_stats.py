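import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps

from seascreen.stats import (
    bonferroni_alpha,
    date_ordinal,
    paired_t,
    pct_higher,
    rank_correlation,
)


def hand_t(diffs):
    """Closed-form paired t oracle: mean/ (sd/sqrt n), p from t_{n-1}."""
    d = np.asarray(diffs, float)
    n = len(d)
    t = d.mean() / (d.std(ddof=1) / math.sqrt(n))
    p = 2 * sps.t.sf(abs(t), n - 1)
    return t, p


def sign_flip_p(diffs):
    """Exact sign-flip permutation p for the paired design (n <= 12)."""
    d = np.asarray(diffs, float)
    n = len(d)
    t_obs = abs(d.mean() / (d.std(ddof=1) / math.sqrt(n)))
    count = 0
    total = 2**n
    for signs in itertools.product((1.0, -1.0), repeat=n):
        dd = d * np.array(signs)
        sd = dd.std(ddof=1)
        t = math.inf if sd == 0 else abs(dd.mean() / (sd / math.sqrt(n)))
        count += t >= t_obs - 1e-12
    return count / total


def test_identical_pairs():
    cmp_ = paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert cmp_.t_stat == 0.0 and cmp_.p_value == 1.0


def test_bonferroni_three_comparisons():
    alpha = bonferroni_alpha(0.05, 3)
    assert alpha == pytest.approx(0.0166667, abs=1e-6)
    assert f"{alpha:.3f}" == "0.017"


def test_paired_t_matches_closed_form_oracle():
    rng = np.random.default_rng(42)
    a = rng.lognormal(1.0, 0.4, 12)
    b = a * 2.0 * rng.lognormal(0, 0.2, 12)
    cmp_ = paired_t(a, b)
    t, p = hand_t(b - a)
    assert cmp_.t_stat == pytest.approx(t, abs=1e-9)
    assert cmp_.p_value == pytest.approx(p, abs=1e-9)


def test_paired_t_consistent_with_sign_flip_permutation():
    rng = np.random.default_rng(5)
    a = rng.normal(10, 1, 10)
    b = a + rng.normal(0.8, 1, 10)
    cmp_ = paired_t(a, b)
    p_perm = sign_flip_p(b - a)
    assert cmp_.p_value == pytest.approx(p_perm, abs=0.05)


def test_paired_t_antisymmetric():
    rng = np.random.default_rng(9)
    a = rng.normal(5, 1, 15)
    b = rng.normal(6, 1, 15)
    fwd = paired_t(a, b)
    rev = paired_t(b, a)
    assert fwd.t_stat == pytest.approx(-rev.t_stat, rel=1e-12)
    assert fwd.p_value == pytest.approx(rev.p_value, rel=1e-12)


def test_incomplete_pairs_dropped():
    a = [1.0, 2.0, np.nan, 4.0]
    b = [1.5, np.nan, 3.0, 4.5]
    cmp_ = paired_t(a, b)
    assert cmp_.n_pairs == 2 and cmp_.n_dropped == 2


def test_rank_correlation_extremes():
    x = [1.0, 2.0, 3.0, 4.0]
    assert rank_correlation([2, 4, 9, 11], x)[0] == pytest.approx(1.0)
    assert rank_correlation([11, 9, 4, 2], x)[0] == pytest.approx(-1.0)


def spearman_oracle(values, covariate):
    """Pearson correlation of average ranks — independent of scipy's
    spearmanr code path."""
    r1 = sps.rankdata(values)  # average-rank ties
    r2 = sps.rankdata(covariate)
    r1 = r1 - r1.mean()
    r2 = r2 - r2.mean()
    return float((r1 @ r2) / math.sqrt((r1 @ r1) * (r2 @ r2)))


def test_rank_correlation_ties_vs_oracle():
    values = [1.0, 2.0, 2.0, 3.0, 5.0, 5.0, 7.0]
    covariate = [10.0, 30.0, 20.0, 20.0, 50.0, 40.0, 60.0]
    rho, p = rank_correlation(values, covariate)
    assert rho == pytest.approx(spearman_oracle(values, covariate), abs=1e-12)
    # exact permutation p over all 7! covariate orderings
    obs = abs(rho)
    count = total = 0
    for perm in itertools.permutations(covariate):
        total += 1
        count += abs(spearman_oracle(values, list(perm))) >= obs - 1e-12
    assert p == pytest.approx(count / total, abs=0.1)


def test_rank_correlation_monotone_invariance():
    rng = np.random.default_rng(13)
    x = rng.normal(size=20)
    y = rng.normal(size=20)
    rho, _ = rank_correlation(x, y)
    # strictly monotone transforms of either argument preserve rho
    rho2, _ = rank_correlation(np.exp(x), y**3)
    assert rho2 == pytest.approx(rho, abs=1e-12)
    rho3, _ = rank_correlation(np.exp(x), 2 * y + 7)
    assert rho3 == pytest.approx(rho, abs=1e-12)


def test_constant_covariate_undefined():
    rho, p = rank_correlation([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])
    assert math.isnan(rho) and math.isnan(p)


def test_pct_higher():
    assert pct_higher(10, 10) == 0.0
    assert pct_higher(10, 30) == 200.0
    with pytest.raises(ValueError):
        pct_higher(0.0, 1.0)


def test_date_ordinal_monotone():
    import datetime as dt

    dates = [dt.date(2015, 6, 1), dt.date(2015, 7, 15), dt.date(2015, 9, 30)]
    ords = date_ordinal(dates)
    assert np.all(np.diff(ords) > 0)


def test_bonferroni_family_wise_error_controlled():
    """On null data, the 3-test family at the corrected threshold keeps
    the family-wise error at or below the nominal 5%."""
    rng = np.random.default_rng(2015)
    n_rep, n_tests, n_pairs = 10_000, 3, 15
    diffs = rng.normal(0.0, 1.0, size=(n_rep, n_tests, n_pairs))
    res = sps.ttest_1samp(diffs, 0.0, axis=2)
    alpha = bonferroni_alpha(0.05, n_tests)
    family_error = np.mean((res.pvalue < alpha).any(axis=1))
    # binomial SE at p=0.05 over 10k replicates is ~0.0022
    assert family_error <= 0.05 + 3 * 0.0022
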