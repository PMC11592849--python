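"""Registry: completeness, density correctness, validation behavior."""

import json
import math
import pathlib

import mpmath as mp
import pytest

from klexact import ParamSet, families_json, get_family, list_families, log_pdf, pdf
from klexact.fixtures import pair_grid

from conftest import integrate_density

EXPECTED_ORDER = [
    # known expressions
    "confluent_hypergeometric_beta", "exponential", "gamma",
    "gauss_hypergeometric_beta", "generalized_gamma", "gumbel", "normal",
    "rayleigh", "weibull",
    # new expressions
    "generalized_uniform", "asymmetric_laplace", "beta", "beta_exponential",
    "beta_prime", "burr", "cauchy", "chi", "chi_square",
    "continuous_bernoulli", "exponentiated_exponential", "f", "frechet",
    "gamma_gompertz", "generalized_beta_first_kind",
    "generalized_beta_second_kind", "generalized_inverse_gaussian",
    "generalized_logistic_1", "generalized_logistic_2",
    "generalized_logistic_3", "generalized_logistic_4", "generalized_pareto",
    "gompertz", "half_cauchy", "half_logistic", "half_normal",
    "half_student_t", "harmonic", "inverse_chi_square",
    "inverse_exponential", "inverse_gamma", "inverse_gaussian",
    "inverse_nakagami", "inverse_rayleigh", "j_shaped", "kumaraswamy",
    "laplace", "libby_novick_beta", "lindley", "logit_normal", "lomax",
    "nakagami", "pareto_1", "power_function_1", "power_function_2",
    "q_exponential", "scaled_inverse_chi_square", "schulz", "student_t",
    "transmuted_exponential", "truncated_normal", "omega",
]


def test_registry_complete_and_ordered():
    fams = list_families()
    assert len(fams) == 61
    assert fams == EXPECTED_ORDER
    assert fams[0] == "confluent_hypergeometric_beta"
    assert fams.count("omega") == 1


@pytest.mark.parametrize(
    "family,params,x,expected",
    [
        ("exponential", {"a": 1.0}, 0.0, 1.0),              # endpoint limit
        ("beta", {"a": 1.0, "b": 1.0}, 0.5, 1.0),           # uniform case
        ("normal", {"a": 1.0, "b": 0.0}, 0.0, 1.0 / math.sqrt(2 * math.pi)),
        ("pareto_1", {"a": 2.0, "K": 1.0}, 0.5, 0.0),       # outside support
    ],
)
def test_pdf_examples(family, params, x, expected):
    assert pdf(family, params, x) == pytest.approx(expected, abs=1e-12)


@pytest.mark.parametrize("family", EXPECTED_ORDER)
def test_density_normalizes(family):
    """Every registry density integrates to one for several parameter sets."""
    fam = get_family(family)
    seen = []
    for p1, p2 in pair_grid(family, 4):
        if p1 not in seen:
            seen.append(p1)
    assert len(seen) >= 3
    for params in seen[:3]:
        values = fam.validate(params)
        total = integrate_density(fam, values)
        assert total == pytest.approx(1.0, abs=1e-8), (family, params)


@pytest.mark.parametrize("family", EXPECTED_ORDER)
def test_logpdf_matches_log_of_pdf(family):
    fam = get_family(family)
    p1, _ = pair_grid(family, 1)[0]
    values = fam.validate(p1)
    lo, hi = fam.support(values)
    a = lo if math.isfinite(lo) else -10.0
    b = hi if math.isfinite(hi) else 10.0
    for t in (0.1, 0.25, 0.5, 0.75, 0.9):
        x = a + t * (b - a)
        p = fam.pdf(values, x)
        if p > 1e-300:
            assert fam.log_pdf(values, x) == pytest.approx(
                math.log(p), abs=1e-10
            )


def test_pdf_zero_outside_support_not_error():
    assert pdf("beta", {"a": 2.0, "b": 2.0}, 1.5) == 0.0
    assert pdf("exponential", {"a": 1.0}, -1.0) == 0.0
    assert log_pdf("exponential", {"a": 1.0}, -1.0) == -math.inf


def test_frechet_no_overflow_near_origin():
    """Log-density deep in the left tail stays finite and accurate."""
    got = log_pdf("frechet", {"a": 1.0, "b": 1.0}, 1e-8)
    with mp.workdps(50):
        x = mp.mpf("1e-8")
        want = float(mp.log(x ** -2 * mp.e ** (-1 / x)))
    assert math.isfinite(got)
    assert got == pytest.approx(want, rel=1e-12)


def test_paramset_validation():
    with pytest.raises(ValueError):
        get_family("not_a_family")
    with pytest.raises(ValueError):
        ParamSet("exponential", {"a": -1.0})
    with pytest.raises(ValueError):
        ParamSet("exponential", {})
    with pytest.raises(ValueError):
        ParamSet("generalized_uniform", {"a": 2.0, "b": 1.0, "c": 1.0})
    with pytest.raises(ValueError):
        ParamSet("continuous_bernoulli", {"a": 1.0})
    # alias (second-density) symbols map onto the same schema
    ps = ParamSet("gamma", {"c": 2.0, "d": 3.0})
    assert ps["a"] == 2.0 and ps["b"] == 3.0


def test_families_json_export_current():
    path = pathlib.Path(__file__).resolve().parents[1] / "families.json"
    on_disk = json.loads(path.read_text())
    assert on_disk == json.loads(families_json())
    assert len(on_disk) == 61
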