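"""Special-function substrate: series, reductions, derivative operators."""

import math

import mpmath as mp
import numpy as np
import pytest
from scipy import special as sp

from klexact.special import (
    EULER_GAMMA,
    DerivPolicy,
    SeriesError,
    SeriesPolicy,
    appell_f1,
    dbessel_k_order,
    dbeta_first,
    dbeta_second,
    dhyp_param,
    dincbeta_first,
    humbert_phi1,
    incbeta,
    param_derivative,
    sum_series,
)


def mp_phi1(a, b, c, x, y, terms=120):
    """Brute-force double sum in extended precision (independent oracle)."""
    with mp.workdps(40):
        tot = mp.mpf(0)
        for m in range(terms):
            for n in range(terms):
                tot += (mp.rf(a, m + n) * mp.rf(b, n) * mp.mpf(x) ** m
                        * mp.mpf(y) ** n / (mp.rf(c, m + n)
                                            * mp.factorial(m) * mp.factorial(n)))
        return float(tot)


def mp_f1(a, b, c, d, x, y, terms=120):
    with mp.workdps(40):
        tot = mp.mpf(0)
        for m in range(terms):
            for n in range(terms):
                tot += (mp.rf(a, m + n) * mp.rf(b, m) * mp.rf(c, n)
                        * mp.mpf(x) ** m * mp.mpf(y) ** n
                        / (mp.rf(d, m + n) * mp.factorial(m) * mp.factorial(n)))
        return float(tot)


@pytest.mark.parametrize("a,b,c,x", [
    (1.0, 2.0, 3.0, 0.4), (0.5, 1.5, 2.0, -0.7), (2.0, 1.0, 4.0, 1.2),
])
def test_phi1_reduces_to_1f1_at_y_zero(a, b, c, x):
    assert humbert_phi1(a, b, c, x, 0.0) == pytest.approx(
        sp.hyp1f1(a, c, x), rel=1e-10
    )


@pytest.mark.parametrize("a,b,c,y", [
    (1.0, 2.0, 3.0, 0.4), (0.5, 1.5, 2.0, -0.6), (2.0, 0.7, 4.0, 0.8),
])
def test_phi1_reduces_to_2f1_at_x_zero(a, b, c, y):
    assert humbert_phi1(a, b, c, 0.0, y) == pytest.approx(
        sp.hyp2f1(a, b, c, y), rel=1e-10
    )


def test_phi1_against_brute_force_double_sum():
    got = humbert_phi1(1.0, 1.0, 2.0, 0.3, 0.2)
    assert got == pytest.approx(mp_phi1(1, 1, 2, 0.3, 0.2), rel=1e-11)


def test_phi1_domain_guard():
    with pytest.raises(ValueError):
        humbert_phi1(1.0, 1.0, 2.0, 0.3, 1.1)
    with pytest.raises(ValueError):
        humbert_phi1(1.0, 1.0, -2.0, 0.3, 0.2)


@pytest.mark.parametrize("a,b,c,d,x", [
    (0.5, 1.0, 1.0, 2.0, 0.4), (2.0, 1.5, 0.7, 3.0, -0.6),
])
def test_appell_f1_reduces_to_2f1_at_y_zero(a, b, c, d, x):
    assert appell_f1(a, b, c, d, x, 0.0) == pytest.approx(
        sp.hyp2f1(a, b, d, x), rel=1e-10
    )


def test_appell_f1_empty_products():
    assert appell_f1(0.7, 1.0, 2.0, 3.0, 0.0, 0.0) == 1.0


def test_appell_f1_against_brute_force_double_sum():
    got = appell_f1(0.5, 1.0, 1.0, 2.0, 0.4, 0.3)
    assert got == pytest.approx(mp_f1(0.5, 1, 1, 2, 0.4, 0.3), rel=1e-11)


def test_appell_f1_domain_guard():
    with pytest.raises(ValueError):
        appell_f1(1.0, 1.0, 1.0, 2.0, 1.2, 0.3)


@pytest.mark.parametrize("f,a0,expected", [
    (lambda a: math.exp(sp.betaln(1 + a, 1.0)), 0.0, -1.0),
    (lambda a: math.exp(2 * a), 0.0, 2.0),
    (lambda a: float(sp.gamma(1 - a)), 0.0, EULER_GAMMA),
])
def test_param_derivative_known_values(f, a0, expected):
    assert param_derivative(f, a0) == pytest.approx(expected, abs=1e-9)


def test_param_derivative_exact_on_polynomials():
    # degree <= 2*levels + 1 is integrated exactly by the Richardson table
    policy = DerivPolicy(richardson_levels=2)
    coeffs = [0.3, -1.2, 2.0, 0.7, -0.4, 0.1]  # degree 5
    p = np.polynomial.Polynomial(coeffs)
    dp = p.deriv()
    for a0 in (-0.7, 0.0, 1.3):
        assert param_derivative(p, a0, policy) == pytest.approx(
            dp(a0), abs=1e-10
        )


def test_dbeta_closed_form_and_symmetry():
    assert dbeta_first(1.0, 1.0) == pytest.approx(-1.0, abs=1e-12)
    # finite-difference oracle on B itself
    h = 1e-6
    fd = (math.exp(sp.betaln(2 + h, 3.0)) - math.exp(sp.betaln(2 - h, 3.0))) / (2 * h)
    assert dbeta_first(2.0, 3.0) == pytest.approx(fd, rel=1e-8)
    for a in (0.5, 1.7):
        assert dbeta_first(a, a) == dbeta_second(a, a)


def test_dbessel_k_order_parity():
    assert dbessel_k_order(0.0, 2.0) == 0.0
    v = dbessel_k_order(1.3, 2.0)
    assert dbessel_k_order(-1.3, 2.0) == pytest.approx(-v, rel=1e-9)
    # Richardson/step-halving consistency oracle
    for h in (1e-4, 5e-5):
        fd = (sp.kv(1.3 + h, 2.0) - sp.kv(1.3 - h, 2.0)) / (2 * h)
        assert v == pytest.approx(fd, rel=1e-6)


def test_dhyp_param_trivial_zeros():
    # 1F1(a;b;0) == 1 for all a; 2F1 likewise at x=0
    assert dhyp_param("f11_a", {"a": 1.0, "b": 2.0, "x": 0.0}) == pytest.approx(
        0.0, abs=1e-10
    )
    assert dhyp_param(
        "f21_c", {"a": 1.0, "b": 2.0, "c": 3.0, "x": 0.0}
    ) == pytest.approx(0.0, abs=1e-10)


def test_dhyp_param_two_routes_agree():
    """Term-wise digamma series vs extended-precision central differences."""
    cases = [
        ("f11_a", {"a": 1.0, "b": 2.0, "x": -0.5}),
        ("f11_b", {"a": 1.5, "b": 2.5, "x": 0.7}),
        ("f21_a", {"a": 1.0, "b": 2.0, "c": 3.0, "x": -0.4}),
        ("f21_b", {"a": 0.5, "b": 1.5, "c": 2.5, "x": 0.5}),
        ("f21_c", {"a": 1.0, "b": 2.0, "c": 3.0, "x": 0.6}),
    ]
    for kind, args in cases:
        got = dhyp_param(kind, args)
        with mp.workdps(40):
            h = mp.mpf("1e-12")
            if kind.startswith("f11"):
                f = lambda e: mp.hyp1f1(
                    args["a"] + e * (kind == "f11_a"),
                    args["b"] + e * (kind == "f11_b"), args["x"],
                )
            else:
                f = lambda e: mp.hyp2f1(
                    args["a"] + e * (kind == "f21_a"),
                    args["b"] + e * (kind == "f21_b"),
                    args["c"] + e * (kind == "f21_c"), args["x"],
                )
            want = float((f(h) - f(-h)) / (2 * h))
        assert got == pytest.approx(want, rel=1e-6), kind


def test_incbeta_against_integral_definition():
    from scipy import integrate

    for (x, a, b) in [(0.5, 2.0, 3.0), (0.3, 0.7, 1.2)]:
        want, _ = integrate.quad(
            lambda t: t ** (a - 1) * (1 - t) ** (b - 1), 0, x
        )
        assert incbeta(x, a, b) == pytest.approx(want, rel=1e-10)
    # parameter derivative vs mpmath quadrature of t^{a-1}(1-t)^{b-1} log t
    with mp.workdps(30):
        want = float(mp.quad(
            lambda t: t ** mp.mpf("1.0") * (1 - t) ** 2 * mp.log(t), [0, 0.5]
        ))
    assert dincbeta_first(0.5, 2.0, 3.0) == pytest.approx(want, rel=1e-7)


def test_series_policy_stopping_rule_and_budget():
    policy = SeriesPolicy(max_terms=10)
    with pytest.raises(SeriesError):
        sum_series(lambda k: 1.0 / k, policy)  # harmonic: never converges
    value, n, bound = sum_series(lambda k: 0.5 ** k, SeriesPolicy())
    assert value == pytest.approx(1.0, abs=1e-12)
    assert bound >= 0.0 and n < 100
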