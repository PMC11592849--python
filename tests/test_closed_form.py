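"""Closed-form divergences: worked values, identities, guards, errata."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import special as sp

import klexact as kx

ALL_FAMILIES = kx.list_families()


@pytest.mark.parametrize(
    "family,p1,p2,expected",
    [
        ("exponential", {"a": 1.0}, {"b": 1.0}, 0.0),
        ("exponential", {"a": 1.0}, {"b": 2.0}, 1.0 - math.log(2.0)),
        ("normal", {"a": 1.0, "b": 0.0}, {"c": 1.0, "d": 1.0}, 0.5),
        ("beta", {"a": 3.0, "b": 2.0}, {"c": 3.0, "d": 2.0}, 0.0),
        ("gamma", {"a": 2.0, "b": 1.0}, {"c": 1.0, "d": 1.0},
         float(sp.digamma(2.0))),
    ],
)
def test_worked_examples(family, p1, p2, expected):
    assert kx.kld(family, p1, p2).value == pytest.approx(expected, abs=1e-12)


@pytest.mark.parametrize("family", ALL_FAMILIES)
def test_identity_zero_and_nonnegative(family, fixture_pairs):
    """KLD(theta, theta) = 0 and KLD >= 0 across the fixture grids."""
    pairs = fixture_pairs(family, 20)
    for p1, _ in pairs[:3]:
        res = kx.kld(family, p1, p1)
        tol = 1e-8 + (res.truncation_bound or 0.0)
        assert abs(res.value) <= tol, (family, p1, res.value)
    for p1, p2 in pairs:
        res = kx.kld(family, p1, p2)
        assert res.value >= -1e-8, (family, p1, p2, res.value)


def test_asymmetry_witness():
    fwd = kx.kld("exponential", {"a": 1.0}, {"b": 2.0}).value
    rev = kx.kld("exponential", {"a": 2.0}, {"b": 1.0}).value
    assert abs(fwd - rev) > 0.1
    for v, pair in ((fwd, ({"a": 1.0}, {"b": 2.0})),
                    (rev, ({"a": 2.0}, {"b": 1.0}))):
        ora, _ = kx.kld_numeric("exponential", pair[0], "exponential", pair[1])
        assert v == pytest.approx(ora, abs=1e-10)


def _normal_row_printed(a, b, c, d):
    # the tabulated normal expression, term by term as printed
    return (math.log(c / a) + d * d / (2 * c * c) - b * b / (2 * a * a)
            + 0.5 * (1 / c ** 2 - 1 / a ** 2) * (a * a + b * b)
            + (b / a ** 2 - d / c ** 2) * b)


def test_normal_row_equals_textbook_form():
    rng = np.random.default_rng(20240959)
    for _ in range(100):
        a, c = rng.uniform(0.2, 3.0, 2)
        b, d = rng.uniform(-3.0, 3.0, 2)
        textbook = kx.kld("normal", {"a": a, "b": b}, {"c": c, "d": d}).value
        assert abs(textbook - _normal_row_printed(a, b, c, d)) < 1e-12


_IDENTITY_GRIDS = {
    "chisq_as_gamma": [{"m": m, "n": n} for m, n in
                       zip(np.linspace(1, 8, 10), np.linspace(8, 1.5, 10))],
    "rayleigh_as_weibull": [{"b": b, "d": d} for b, d in
                            zip(np.linspace(0.4, 2.5, 10),
                                np.linspace(2.2, 0.5, 10))],
    "exponential_as_gamma": [{"a": a, "b": b} for a, b in
                             zip(np.linspace(0.3, 4, 10),
                                 np.linspace(3.5, 0.4, 10))],
    "powerfn1_as_beta": [{"a": a, "b": b} for a, b in
                         zip(np.linspace(0.5, 5, 10),
                             np.linspace(4.5, 0.6, 10))],
    "genlogistic1_matches_exponential_form": [
        {"a": a, "b": b} for a, b in
        zip(np.linspace(0.5, 4, 10), np.linspace(3.8, 0.7, 10))],
    "generalized_gamma_to_weibull": [
        {"a": a, "b": b, "c": c, "d": d} for a, b, c, d in
        zip(np.linspace(0.7, 2.5, 10), np.linspace(0.5, 2.0, 10),
            np.linspace(2.2, 0.8, 10), np.linspace(1.8, 0.6, 10))],
    "inverse_exponential_as_inverse_gamma": [
        {"a": a, "b": b} for a, b in
        zip(np.linspace(0.3, 4, 10), np.linspace(3.5, 0.4, 10))],
}


@pytest.mark.parametrize("identity", sorted(_IDENTITY_GRIDS))
def test_reduction_identities(identity):
    """The seven inter-family identities hold on 10-point grids."""
    for params in _IDENTITY_GRIDS[identity]:
        lhs, rhs = kx.kld_reduced(identity, params)
        assert lhs.value == pytest.approx(rhs.value, abs=1e-8), params


def test_reduction_identity_oracle_confirmed():
    lhs, rhs = kx.kld_reduced("chisq_as_gamma", {"m": 3.0, "n": 5.0})
    assert lhs.value == pytest.approx(rhs.value, abs=1e-10)
    ora, _ = kx.kld_numeric("chi_square", {"m": 3.0}, "chi_square", {"n": 5.0})
    assert lhs.value == pytest.approx(ora, abs=1e-8)


def test_unknown_identity_raises():
    with pytest.raises(ValueError):
        kx.kld_reduced("not_an_identity", {})


def test_convergence_guard_arithmetic():
    ok, reason = kx.convergence_guard("cauchy", {"sigma": 1.0}, {"r": 2.0})
    assert not ok and "1 - r^2/sigma^2" in reason
    ok, _ = kx.convergence_guard("cauchy", {"sigma": 1.0}, {"r": 1.2})
    assert ok
    ok, _ = kx.convergence_guard(
        "student_t", {"n": 3.0, "sigma": 1.5}, {"p": 3.0, "r": 1.5}
    )
    assert ok  # series collapses to its first term


def test_guarded_point_falls_back_to_oracle():
    res = kx.kld("cauchy", {"sigma": 1.0}, {"r": 2.0})
    assert res.method == "oracle_fallback"
    assert any("convergence_guard" in w for w in res.warnings)
    # two zero-median Cauchys have an elementary divergence to check against
    assert res.value == pytest.approx(math.log(9.0 / 8.0), abs=1e-8)


@pytest.mark.parametrize("sigma,r", [(1.0, 1.2), (1.0, 0.8), (2.0, 2.3)])
def test_cauchy_series_matches_elementary_form(sigma, r):
    """The tabulated series sums to log((sigma+r)^2 / (4 sigma r))."""
    res = kx.kld("cauchy", {"sigma": sigma}, {"r": r})
    assert res.method == "closed_series"
    want = math.log((sigma + r) ** 2 / (4.0 * sigma * r))
    assert res.value == pytest.approx(want, abs=1e-10)


def test_shared_parameter_mismatch_rejected():
    with pytest.raises(ValueError):
        kx.kld("pareto_1", {"a": 2.0, "K": 1.0}, {"b": 3.0, "K": 2.0})
    with pytest.raises(ValueError):
        kx.kld("truncated_normal",
               {"a": 1.0, "b": 0.0, "L": -1.0, "U": 1.0},
               {"c": 1.0, "d": 0.0, "L": -2.0, "U": 1.0})


def test_exponentiated_exponential_erratum():
    """The literal printed form disagrees with the oracle; the corrected
    exponent (c-1, not b-1) agrees."""
    p1 = {"a": 2.0, "b": 1.0}
    p2 = {"c": 3.0, "d": 1.3}
    corrected = kx.kld("exponentiated_exponential", p1, p2).value
    verbatim = kx.kld_paper_verbatim("exponentiated_exponential", p1, p2)
    ora, _ = kx.kld_numeric("exponentiated_exponential", p1,
                            "exponentiated_exponential", p2)
    assert corrected == pytest.approx(ora, abs=1e-8)
    assert abs(verbatim - ora) > 1e-3
    assert "exponentiated_exponential" in kx.ERRATA


def test_q_exponential_routes_through_exponential_limit():
    # a = c = 1 is the exponential limit of the family
    res = kx.kld("q_exponential", {"a": 1.0, "b": 1.0}, {"c": 1.0, "d": 2.0})
    assert res.value == pytest.approx(1.0 - math.log(2.0), abs=1e-12)


def test_result_dataclass_diagnostics():
    res = kx.kld("cauchy", {"sigma": 1.0}, {"r": 1.2})
    assert res.series_terms_used is not None and res.series_terms_used > 0
    assert res.truncation_bound is not None and res.truncation_bound >= 0.0
    assert float(res) == res.value


@settings(deadline=None, max_examples=40, derandomize=True)
@given(
    a=st.floats(0.2, 4.0), b=st.floats(-3.0, 3.0),
    c=st.floats(0.2, 4.0), d=st.floats(-3.0, 3.0),
)
def test_normal_kld_nonnegative_and_zero_iff_equal(a, b, c, d):
    val = kx.kld("normal", {"a": a, "b": b}, {"c": c, "d": d}).value
    assert val >= -1e-12
    if a == c and b == d:
        assert val == pytest.approx(0.0, abs=1e-12)
    elif abs(a - c) > 1e-3 or abs(b - d) > 1e-3:
        assert val > 0.0


@settings(deadline=None, max_examples=30, derandomize=True)
@given(a=st.floats(0.1, 10.0), b=st.floats(0.1, 10.0))
def test_exponential_form_families_share_one_expression(a, b):
    """Several rows collapse to log(a/b)+b/a-1; they must agree exactly."""
    want = math.log(a / b) + b / a - 1.0
    for family in ("exponential", "generalized_logistic_1",
                   "power_function_1", "power_function_2",
                   "inverse_exponential", "half_logistic", "j_shaped"):
        got = kx.kld(family, {"a": a}, {"b": b}).value
        assert got == pytest.approx(want, rel=1e-12, abs=1e-12), family
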