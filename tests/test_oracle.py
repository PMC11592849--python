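"""Quadrature oracle: sanity, orientation, supports, tolerance behavior."""

import math
import warnings

import pytest

import klexact as kx
from klexact import QuadratureSettings


@pytest.mark.parametrize("family", kx.list_families())
def test_identical_parameters_integrate_to_zero(family, fixture_pairs):
    p1, _ = fixture_pairs(family, 1)[0]
    settings = QuadratureSettings()
    val, err = kx.kld_numeric(family, p1, family, p1, settings=settings)
    assert abs(val) <= 2 * max(settings.abs_tol, err + 1e-12), (family, p1)


def test_known_elementary_integrals():
    val, _ = kx.kld_numeric("exponential", {"a": 1.0}, "exponential", {"b": 2.0})
    assert val == pytest.approx(1.0 - math.log(2.0), abs=1e-10)
    val, _ = kx.kld_numeric("normal", {"a": 1.0, "b": 0.0},
                            "normal", {"c": 1.0, "d": 1.0})
    assert val == pytest.approx(0.5, abs=1e-10)


def test_orientation_matters():
    a, _ = kx.kld_numeric("normal", {"a": 1.0, "b": 0.0},
                          "normal", {"c": 2.0, "d": 1.0})
    b, _ = kx.kld_numeric("normal", {"a": 2.0, "b": 1.0},
                          "normal", {"c": 1.0, "d": 0.0})
    assert abs(a - b) > 1e-3


def test_support_violation_is_infinite_with_warning():
    with warnings.catch_warnings(record=True) as rec:
        warnings.simplefilter("always")
        val, err = kx.kld_numeric("pareto_1", {"a": 2.0, "K": 1.0},
                                  "pareto_1", {"b": 2.0, "K": 2.0})
    assert math.isinf(val)
    assert any("support" in str(w.message) for w in rec)
    # nested the other way the divergence is finite: 2*log(2) exactly
    val, _ = kx.kld_numeric("pareto_1", {"a": 2.0, "K": 2.0},
                            "pareto_1", {"b": 2.0, "K": 1.0})
    assert val == pytest.approx(2.0 * math.log(2.0), abs=1e-9)


def test_cross_family_calls_supported():
    # gamma with unit shape is the exponential: values must coincide
    val, _ = kx.kld_numeric("exponential", {"a": 1.5},
                            "gamma", {"a": 1.0, "b": 0.5})
    want = kx.kld("exponential", {"a": 1.5}, {"b": 0.5}).value
    assert val == pytest.approx(want, abs=1e-9)


def test_halving_tolerance_consistent_with_error_estimate():
    base = QuadratureSettings()
    tight = QuadratureSettings(rel_tol=base.rel_tol / 2.0)
    for family, p1, p2 in [
        ("gamma", {"a": 2.0, "b": 1.0}, {"c": 1.0, "d": 1.0}),
        ("student_t", {"n": 3.0, "sigma": 1.0}, {"p": 4.0, "r": 1.2}),
    ]:
        v1, e1 = kx.kld_numeric(family, p1, family, p2, settings=base)
        v2, _ = kx.kld_numeric(family, p1, family, p2, settings=tight)
        assert abs(v1 - v2) <= max(e1, 1e-12)


def test_heavy_tail_mass_not_lost():
    """Power-law tails (inverse chi-square with tiny dof) are captured."""
    val, _ = kx.kld_numeric("inverse_chi_square", {"m": 0.5},
                            "inverse_chi_square", {"n": 2.0})
    want = kx.kld("inverse_chi_square", {"m": 0.5}, {"n": 2.0}).value
    assert val == pytest.approx(want, abs=1e-8)
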