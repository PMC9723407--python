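import numpy as np
import pytest
from scipy import stats as sp_stats

from nremscope.stats import (bf10_ttest, interpret_bf10, moderated_regression,
                             paired_t, pearson_r, remove_outliers, welch_t)
from nremscope.validation import bf10_nct_oracle

RNG = np.random.default_rng(123)
X = RNG.normal(0, 1.0, 20)
Y = RNG.normal(0.5, 1.4, 25)


def test_welch_t_matches_scipy():
    res = welch_t(X, Y)
    ref = sp_stats.ttest_ind(X, Y, equal_var=False)
    assert res.statistic == pytest.approx(ref.statistic, abs=1e-10)
    assert res.p == pytest.approx(ref.pvalue, abs=1e-10)
    assert res.n1 == 20 and res.n2 == 25


def test_welch_reduces_to_student_under_equal_variances():
    y = X + 1.0                     # equal n, identical sample variance
    res = welch_t(X, y)
    ref = sp_stats.ttest_ind(X, y, equal_var=True)
    assert res.statistic == pytest.approx(ref.statistic, abs=1e-10)
    assert res.p == pytest.approx(ref.pvalue, abs=1e-10)
    assert res.df == pytest.approx(2 * len(X) - 2, abs=1e-8)


def test_welch_degenerate_and_small_inputs():
    zero = welch_t([1.0, 1.0, 1.0], [1.0, 1.0])
    assert zero.statistic == 0.0 and zero.p == 1.0
    assert "zero variance" in zero.note
    with pytest.raises(ValueError):
        welch_t([1.0], [1.0, 2.0])


def test_paired_t_matches_scipy():
    y = Y[:20]
    res = paired_t(X, y)
    ref = sp_stats.ttest_rel(X, y)
    assert res.statistic == pytest.approx(ref.statistic, abs=1e-10)
    assert res.p == pytest.approx(ref.pvalue, abs=1e-10)
    assert res.df == len(X) - 1


def test_paired_t_degenerate_differences():
    res = paired_t(X, X.copy())     # zero difference for every pair
    assert res.statistic is None and res.p is None
    assert "zero variance" in res.note
    with pytest.raises(ValueError):
        paired_t(X, Y)              # unequal lengths


def test_pearson_r_matches_scipy():
    res = pearson_r(X, Y[:20])
    r_ref, p_ref = sp_stats.pearsonr(X, Y[:20])
    assert res.r == pytest.approx(r_ref, abs=1e-10)
    assert res.p == pytest.approx(p_ref, abs=1e-10)
    assert res.df == 18


def test_pearson_exact_linear_relations():
    x = np.arange(10.0)
    res = pearson_r(x, -2 * x + 3)
    assert res.r == -1.0 and res.p == 0.0
    with pytest.raises(ValueError):
        pearson_r(x, np.ones(10))


def test_bf10_matches_independent_oracle():
    for t, n1, n2 in ((1.5, 20, 20), (2.5, 15, 25), (0.0, 10, None)):
        assert bf10_ttest(t, n1, n2) == pytest.approx(
            bf10_nct_oracle(t, n1, n2), rel=1e-6)


def test_bf10_monotone_in_t():
    vals = [bf10_ttest(t, 20, 20) for t in (0.0, 0.5, 1.0, 2.0, 3.0, 4.0)]
    assert np.all(np.diff(vals) > 0)
    with pytest.raises(ValueError):
        bf10_ttest(np.inf, 20, 20)


def test_interpret_bf10_bins():
    assert interpret_bf10(0.5) == "null-favoring"
    assert interpret_bf10(2) == "anecdotal"
    assert interpret_bf10(5) == "moderate"
    assert interpret_bf10(20) == "strong"
    assert interpret_bf10(50) == "very strong"
    assert interpret_bf10(500) == "extreme"


def test_remove_outliers():
    x = np.r_[RNG.normal(0, 1, 50), 100.0]
    kept, removed = remove_outliers(x)
    assert removed.tolist() == [50]
    assert len(kept) == 50
    # nothing removed from data wholly within mean +/- 3 SD
    kept2, removed2 = remove_outliers(kept)
    assert removed2.size == 0
    np.testing.assert_array_equal(kept2, kept)
    const, r = remove_outliers(np.ones(5))
    assert r.size == 0
    with pytest.raises(ValueError):
        remove_outliers([1.0, 2.0])


def test_moderated_regression_recovers_coefficients():
    rng = np.random.default_rng(5)
    x = rng.normal(0, 1, 200)
    m = rng.normal(0, 1, 200)
    y = 2.0 + 3.0 * x + rng.normal(0, 0.1, 200)
    res = moderated_regression(y, x, m)
    assert res.terms["x"]["b"] == pytest.approx(3.0, abs=0.1)
    assert res.terms["intercept"]["b"] == pytest.approx(2.0, abs=0.1)
    assert res.terms["interaction"]["p"] > 0.01
    assert res.r_squared > 0.99


def test_moderated_regression_centering_invariance():
    rng = np.random.default_rng(6)
    x = rng.normal(2, 1, 100)
    m = rng.normal(-1, 1, 100)
    y = 1.0 + 0.5 * x - 0.3 * m + 0.4 * x * m + rng.normal(0, 0.5, 100)
    raw = moderated_regression(y, x, m)
    cen = moderated_regression(y, x - x.mean(), m - m.mean())
    assert cen.terms["interaction"]["t"] == pytest.approx(
        raw.terms["interaction"]["t"], abs=1e-8)


def test_moderated_regression_degenerate_and_errors():
    x = np.arange(10.0)
    flat = moderated_regression(np.full(10, 7.0), x, x ** 2)
    assert flat.r_squared == 0.0
    assert flat.terms["x"]["b"] == 0.0
    assert flat.terms["intercept"]["b"] == 7.0
    with pytest.raises(ValueError, match="rank"):
        moderated_regression(x, x, x)    # moderator duplicates x
    with pytest.raises(ValueError):
        moderated_regression(x[:4], x[:4], x[:4])


def test_p_value_never_zero():
    res = welch_t(np.arange(20.0), np.arange(20.0) + 1000.0)
    assert res.p > 0.0
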