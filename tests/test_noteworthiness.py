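import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate, stats

from oralmicro.noteworthiness import (annotate_noteworthiness, bfdp,
                                      default_prior_variance, flag_noteworthy,
                                      fprp, power_at_alternative)


def bfdp_quadrature(theta_hat, se, prior, w):
    """Oracle: posterior null probability by numerical integration of the
    null density N(theta_hat; 0, V) against the marginal alternative
    density integral N(theta_hat; theta, V) N(theta; 0, W) dtheta."""
    v = se ** 2
    null = stats.norm.pdf(theta_hat, 0, np.sqrt(v))
    alt, _ = integrate.quad(
        lambda th: stats.norm.pdf(theta_hat, th, np.sqrt(v))
        * stats.norm.pdf(th, 0, np.sqrt(w)),
        -np.inf, np.inf)
    num = null * (1 - prior)
    return num / (num + alt * prior)


def test_power_null_alternative_equals_alpha():
    for alpha in (0.01, 0.05, 0.2):
        assert power_at_alternative(alpha, se=0.3, theta1=0.0) == \
            pytest.approx(alpha, abs=1e-12)


def test_power_tends_to_one_as_se_shrinks():
    assert power_at_alternative(0.05, se=1e-6, theta1=np.log(1.5)) == \
        pytest.approx(1.0)


def test_power_symmetric_in_effect_sign():
    a = power_at_alternative(0.05, 0.2, np.log(1.5))
    b = power_at_alternative(0.05, 0.2, -np.log(1.5))
    assert a == pytest.approx(b)


def test_power_matches_monte_carlo_z_test():
    alpha, se, theta1 = 0.05, 0.2, np.log(1.5)
    rng = np.random.default_rng(123)
    n = 10 ** 6
    z = rng.normal(theta1 / se, 1.0, size=n)
    c = stats.norm.ppf(1 - alpha / 2)
    mc = np.mean(np.abs(z) > c)
    se_mc = np.sqrt(mc * (1 - mc) / n)
    assert abs(power_at_alternative(alpha, se, theta1) - mc) < 3 * se_mc


def test_fprp_certain_prior_gives_zero():
    assert fprp(0.01, 0.2, prior=1.0) == 0.0


def test_fprp_null_alternative_identity():
    # power equals alpha when theta1 = 0, so FPRP = 1 - prior
    for prior in (0.01, 0.3, 0.9):
        assert fprp(0.03, 0.2, prior, rr1=1.0) == pytest.approx(1 - prior)


def test_fprp_worked_value():
    # alpha = 0.001, SE = 0.2, prior = 0.01, RR1 = 1.5
    val = fprp(0.001, 0.2, 0.01, rr1=1.5)
    power = power_at_alternative(0.001, 0.2, np.log(1.5))
    expected = 0.001 * 0.99 / (0.001 * 0.99 + power * 0.01)
    assert val == pytest.approx(expected, abs=1e-12)
    assert val == pytest.approx(0.49, abs=0.01)


def test_fprp_stable_for_extreme_p_values():
    """Very small observed p-values (strong depletions) must drive FPRP
    toward 0, not underflow the power term to 0 and FPRP to 1."""
    assert fprp(1e-69, 0.12, prior=0.01) < 1e-12
    assert fprp(1e-300, 0.12, prior=0.01) < 1e-12


@settings(deadline=None, max_examples=200)
@given(st.floats(1e-6, 0.5), st.floats(0.01, 2.0),
       st.floats(0.001, 0.5), st.floats(0.001, 0.5))
def test_fprp_decreasing_in_prior(alpha, se, pi_lo, delta):
    pi_hi = min(pi_lo + delta, 0.999)
    assert fprp(alpha, se, pi_hi) <= fprp(alpha, se, pi_lo) + 1e-12


def test_bfdp_point_null_prior_variance():
    abf, val = bfdp(theta_hat=0.7, se=0.2, prior=0.3, w=0.0)
    assert abf == pytest.approx(1.0)
    assert val == pytest.approx(0.7)


def test_bfdp_zero_estimate_favors_null():
    for w in (0.01, 0.1, 1.0):
        abf, val = bfdp(0.0, 0.2, prior=0.2, w=w)
        assert abf >= 1.0
        assert val >= 1 - 0.2


def test_bfdp_worked_value():
    w = default_prior_variance(1.5)
    _, val = bfdp(np.log(0.5), 0.2, prior=0.01, w=w)
    assert val == pytest.approx(bfdp_quadrature(np.log(0.5), 0.2, 0.01, w),
                                abs=1e-6)
    assert val == pytest.approx(0.86, abs=0.01)


@pytest.mark.parametrize("theta_hat", [-0.7, -0.2, 0.0, 0.4, 1.1])
@pytest.mark.parametrize("se", [0.1, 0.25, 0.6])
@pytest.mark.parametrize("w", [0.01, 0.0428, 0.25])
def test_bfdp_matches_quadrature_grid(theta_hat, se, w):
    _, val = bfdp(theta_hat, se, prior=0.01, w=w)
    assert val == pytest.approx(bfdp_quadrature(theta_hat, se, 0.01, w),
                                abs=1e-6)


@settings(deadline=None, max_examples=200)
@given(st.floats(-3, 3), st.floats(0.01, 3), st.floats(0.001, 0.999),
       st.floats(0, 2))
def test_probabilities_bounded(theta_hat, se, prior, w):
    _, b = bfdp(theta_hat, se, prior, w=w)
    assert 0.0 <= b <= 1.0
    f = fprp(max(min(2 * stats.norm.sf(abs(theta_hat / se)), 1.0), 1e-12),
             se, prior)
    assert 0.0 <= f <= 1.0


@pytest.mark.parametrize("bh,f,b,expected", [
    (False, 0.01, 0.01, False),        # not BH-significant: never noteworthy
    (True, 0.4, 0.4, True),            # both < 0.5
    (True, 0.6, 0.19, True),           # BFDP < 0.2 alone
    (True, 0.19, 0.6, True),           # FPRP < 0.2 alone
    (True, 0.6, 0.6, False),
    (True, 0.4, 0.6, False),           # one < 0.5 is not enough
])
def test_noteworthy_rule(bh, f, b, expected):
    assert flag_noteworthy(bh, f, b) is expected


def test_annotate_adds_columns_per_prior():
    df = pd.DataFrame({
        "taxon_id": ["a", "b"],
        "log_rr": [np.log(0.2), np.nan],
        "se": [0.15, np.nan],
        "p_value": [1e-8, np.nan],
        "bh_significant": [True, False],
    })
    out = annotate_noteworthiness(df)
    for pi in (0.001, 0.01, 0.05):
        assert f"fprp_pi{pi:g}" in out.columns
        assert f"bfdp_pi{pi:g}" in out.columns
    assert bool(out.loc[0, "noteworthy"])
    assert not out.loc[1, "noteworthy"]
    assert np.isnan(out.loc[1, "fprp_pi0.01"])
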