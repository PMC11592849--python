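"""Special-function substrate for the closed-form divergences.

The divergence expressions use, beyond what scipy ships directly:

* the Humbert ``Phi1`` and Appell ``F1`` double hypergeometric series,
* derivatives of ``1F1``/``2F1``/``F1`` with respect to a *parameter* slot
  (the ``d/d(alpha) [.]|_{alpha=0}`` device used throughout the tables),
* the derivative of the modified Bessel function ``K_nu(x)`` with respect
  to its order,
* parameter derivatives of the beta and incomplete beta functions.

Every derivative operator has two independent evaluation routes — a
term-wise (digamma-weighted) series and Richardson-extrapolated central
differences — so silent inaccuracy in these terms can be caught by the
agreement checks in the test-suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import mpmath as mp
import numpy as np
from scipy import integrate
from scipy import special as sp

__all__ = [
    "EULER_GAMMA",
    "SeriesPolicy",
    "DerivPolicy",
    "SeriesError",
    "sum_series",
    "sum_powerlaw_series",
    "humbert_phi1",
    "appell_f1",
    "param_derivative",
    "dbeta_first",
    "dbeta_second",
    "dbessel_k_order",
    "dhyp_param",
    "dincbeta_first",
    "dincbeta_second",
]

EULER_GAMMA = float(mp.euler)


class SeriesError(RuntimeError):
    """A series did not converge within its policy budget."""


@dataclass(frozen=True)
class SeriesPolicy:
    """Truncation policy for the infinite sums in the divergence tables."""

    rel_tol: float = 1e-12
    abs_tol: float = 1e-15
    max_terms: int = 100_000
    consecutive_small: int = 3

    def threshold(self, partial: float) -> float:
        return max(self.abs_tol, self.rel_tol * abs(partial))


@dataclass(frozen=True)
class DerivPolicy:
    """Finite-difference policy for parameter derivatives.

    The default step balances roundoff against the O(h^(2L+2)) truncation
    of an L-level Richardson table: eps^(1/(2L+3)), scaled by max(1,|a0|).
    (A bare central difference would want eps^(1/3); with the default two
    Richardson levels that step leaves roundoff noise dominant.)
    """

    scheme: str = "central_difference"
    step: float | None = None
    richardson_levels: int = 2

    def step_for(self, a0: float) -> float:
        if self.step is not None:
            return self.step
        expo = 1.0 / (2.0 * self.richardson_levels + 3.0)
        return (np.finfo(float).eps ** expo) * max(1.0, abs(a0))


DEFAULT_SERIES = SeriesPolicy()
DEFAULT_DERIV = DerivPolicy()


# ---------------------------------------------------------------------------
# generic summation
# ---------------------------------------------------------------------------

def sum_series(term, policy: SeriesPolicy = DEFAULT_SERIES, start: int = 1):
    """Sum ``term(k)`` for k = start, start+1, ... under the stopping rule.

    Stops after ``consecutive_small`` successive terms below
    ``max(abs_tol, rel_tol*|partial|)``.  Returns ``(value, n_terms, bound)``
    where ``bound`` is the heuristic truncation bound (magnitude of the last
    included term times ``consecutive_small``).
    """
    total = 0.0
    small = 0
    last = 0.0
    k = start
    for n in range(policy.max_terms):
        t = term(k)
        total += t
        last = t
        if abs(t) <= policy.threshold(total):
            small += 1
            if small >= policy.consecutive_small:
                return total, n + 1, abs(t) * policy.consecutive_small
        else:
            small = 0
        k += 1
    raise SeriesError(
        f"series did not converge within {policy.max_terms} terms "
        f"(last term {last:.3e})"
    )


def sum_asymptotic(term, policy: SeriesPolicy = DEFAULT_SERIES):
    """Optimal truncation of an asymptotic series.

    Sums ``term(k)`` while the magnitudes decrease, stopping early at the
    usual tolerance; if terms start growing before the tolerance is met the
    sum is truncated at the smallest term and that term's magnitude is the
    returned error bound.
    """
    total = 0.0
    last = math.inf
    small = 0
    for k in range(1, policy.max_terms + 1):
        t = term(k)
        if not np.isfinite(t):
            raise SeriesError(f"asymptotic series term {k} not finite")
        if abs(t) > last:
            return total, k - 1, last
        total += t
        last = abs(t)
        if abs(t) <= policy.threshold(total):
            small += 1
            if small >= policy.consecutive_small:
                return total, k, abs(t) * policy.consecutive_small
        else:
            small = 0
    raise SeriesError("asymptotic series: no turning point within budget")


def sum_powerlaw_series(term, policy: SeriesPolicy = DEFAULT_SERIES,
                        head: int = 400):
    """Sum a series whose terms decay like a power law ``k**(-1-c)``.

    ``term`` must accept non-integer arguments.  The first ``head`` terms are
    summed directly; the tail is estimated with the Euler--Maclaurin formula
    (integral by adaptive quadrature plus endpoint corrections with
    finite-difference derivatives).  Falls back to plain summation if it
    converges inside the head.
    """
    total = 0.0
    small = 0
    for k in range(1, head + 1):
        t = term(float(k))
        total += t
        if abs(t) <= policy.threshold(total):
            small += 1
            if small >= policy.consecutive_small:
                return total, k, abs(t) * policy.consecutive_small
        else:
            small = 0
    k0 = head + 1
    tail_int, tail_err = integrate.quad(
        term, k0, np.inf, epsabs=policy.abs_tol, epsrel=1e-10, limit=200
    )
    h = 1e-2 * k0
    d1 = (term(k0 + h) - term(k0 - h)) / (2 * h)
    d3 = (term(k0 + 2 * h) - 2 * term(k0 + h) + 2 * term(k0 - h)
          - term(k0 - 2 * h)) / (2 * h ** 3)
    tail = tail_int + 0.5 * term(k0) - d1 / 12.0 + d3 / 720.0
    bound = abs(tail_err) + abs(d3 / 720.0) + abs(term(k0)) * 1e-8
    return total + tail, head, bound


# ---------------------------------------------------------------------------
# double hypergeometric series
# ---------------------------------------------------------------------------

def humbert_phi1(a: float, b: float, c: float, x: float, y: float,
                 policy: SeriesPolicy = DEFAULT_SERIES) -> float:
    """Humbert ``Phi1(a,b,c;x,y)``, the degenerate two-variable series.

    ``Phi1 = sum_{m,n} (a)_{m+n} (b)_n x^m y^n / ((c)_{m+n} m! n!)``;
    requires ``|y| < 1`` (the x-direction is entire).
    """
    if c <= 0 and c == int(c):
        raise ValueError("c must not be a nonpositive integer")
    if abs(y) >= 1:
        raise ValueError(f"Humbert Phi1 requires |y|<1, got y={y}")

    def inner(n: int) -> float:
        # sum over m of (a)_{m+n}/( (c)_{m+n} m! ) x^m  = ratio * 1F1-style
        # computed by direct recursion in m
        tot = 0.0
        term = 1.0
        m = 0
        small = 0
        while m < policy.max_terms:
            tot += term
            if abs(term) <= policy.threshold(tot):
                small += 1
                if small >= policy.consecutive_small:
                    break
            else:
                small = 0
            term *= (a + m + n) / (c + m + n) * x / (m + 1)
            m += 1
        else:
            raise SeriesError("Phi1 inner series did not converge")
        return tot

    total = 0.0
    pref = 1.0  # (a)_n (b)_n y^n / ((c)_n n!)
    small = 0
    for n in range(policy.max_terms):
        t = pref * inner(n)
        total += t
        if abs(t) <= policy.threshold(total):
            small += 1
            if small >= policy.consecutive_small:
                return total
        else:
            small = 0
        pref *= (a + n) * (b + n) / ((c + n) * (n + 1)) * y
    raise SeriesError("Phi1 outer series did not converge")


def appell_f1(a: float, b: float, c: float, d: float, x: float, y: float,
              policy: SeriesPolicy = DEFAULT_SERIES) -> float:
    """Appell ``F1(a,b,c;d;x,y)`` by its double series; needs |x|,|y| < 1."""
    if d <= 0 and d == int(d):
        raise ValueError("d must not be a nonpositive integer")
    if abs(x) >= 1 or abs(y) >= 1:
        raise ValueError(f"Appell F1 series requires |x|,|y|<1, got {x}, {y}")

    total = 0.0
    small = 0
    outer = 1.0  # (a)_n (c)_n y^n / ((d)_n n!)
    for n in range(policy.max_terms):
        # inner sum over m: (a+n)_m (b)_m x^m / ((d+n)_m m!) = 2F1 truncated
        tot = 0.0
        term = 1.0
        m = 0
        ismall = 0
        while m < policy.max_terms:
            tot += term
            if abs(term) <= policy.threshold(tot):
                ismall += 1
                if ismall >= policy.consecutive_small:
                    break
            else:
                ismall = 0
            term *= (a + n + m) * (b + m) / ((d + n + m) * (m + 1)) * x
            m += 1
        else:
            raise SeriesError("F1 inner series did not converge")
        t = outer * tot
        total += t
        if abs(t) <= policy.threshold(total):
            small += 1
            if small >= policy.consecutive_small:
                return total
        else:
            small = 0
        outer *= (a + n) * (c + n) / ((d + n) * (n + 1)) * y
    raise SeriesError("F1 outer series did not converge")


# ---------------------------------------------------------------------------
# derivative operators
# ---------------------------------------------------------------------------

def _central_diff(f, a0: float, h: float, levels: int) -> tuple[float, float]:
    """Richardson table for the central difference; returns (value, last_gap)."""
    rows = []
    for i in range(levels + 1):
        hi = h / (2.0 ** i)
        rows.append((f(a0 + hi) - f(a0 - hi)) / (2.0 * hi))
    table = [rows]
    for lvl in range(1, levels + 1):
        prev = table[-1]
        fac = 4.0 ** lvl
        table.append(
            [(fac * prev[i + 1] - prev[i]) / (fac - 1.0)
             for i in range(len(prev) - 1)]
        )
    best = table[-1][0]
    gap = abs(best - table[-2][0]) if levels >= 1 else math.nan
    return best, gap


def param_derivative(f, a0: float, policy: DerivPolicy = DEFAULT_DERIV,
                     warnings: list | None = None) -> float:
    """``df/d(alpha)`` at ``a0`` by Richardson-extrapolated central differences."""
    h = policy.step_for(a0)
    val, gap = _central_diff(f, a0, h, policy.richardson_levels)
    if not np.isfinite(val):
        raise ValueError(f"function not finite near alpha0={a0}")
    if warnings is not None and np.isfinite(gap):
        if gap > 1e-7 * max(1.0, abs(val)):
            warnings.append(
                f"derivative Richardson levels disagree ({gap:.2e}) at {a0}"
            )
    return val


def dbeta_first(a: float, b: float) -> float:
    """``d B(a,b) / da = B(a,b) (psi(a) - psi(a+b))`` (closed form)."""
    if a <= 0 or b <= 0:
        raise ValueError("beta arguments must be positive")
    return math.exp(sp.betaln(a, b)) * (sp.digamma(a) - sp.digamma(a + b))


def dbeta_second(a: float, b: float) -> float:
    """``d B(a,b) / db`` (symmetric partner of :func:`dbeta_first`)."""
    return dbeta_first(b, a)


def dbessel_k_order(p: float, x: float,
                    policy: DerivPolicy = DEFAULT_DERIV) -> float:
    """``d K_nu(x) / d nu`` at ``nu = p`` (odd in p; 0 at p = 0)."""
    if x <= 0:
        raise ValueError("x must be positive")
    if p == 0.0:
        return 0.0
    with mp.workdps(30):
        val = mp.diff(lambda v: mp.besselk(v, x), p, h=10 ** -6)
    val = float(val)
    if not np.isfinite(val):
        raise OverflowError(f"dK/dnu overflowed at nu={p}, x={x}")
    return val


def dlog_besselk_order(p: float, x: float) -> float:
    """``d log K_nu(x) / d nu`` at ``nu = p`` (what the GIG row consumes)."""
    if p == 0.0:
        return 0.0
    with mp.workdps(30):
        val = mp.diff(lambda v: mp.log(mp.besselk(v, x)), p, h=10 ** -6)
    return float(val)


# --- parameter derivatives of 1F1 / 2F1 / Appell slots ----------------------

def _poch_ratio_terms(kind: str, args: dict, k: int) -> float:
    """Digamma weight of term k for the requested parameter slot."""
    if kind == "f11_a":
        a = args["a"]
        return sp.digamma(a + k) - sp.digamma(a)
    if kind == "f11_b":
        b = args["b"]
        return -(sp.digamma(b + k) - sp.digamma(b))
    if kind == "f21_a":
        a = args["a"]
        return sp.digamma(a + k) - sp.digamma(a)
    if kind == "f21_b":
        b = args["b"]
        return sp.digamma(b + k) - sp.digamma(b)
    if kind == "f21_c":
        c = args["c"]
        return -(sp.digamma(c + k) - sp.digamma(c))
    raise ValueError(f"unknown slot {kind!r}")


def _hyp_termwise(kind: str, args: dict, policy: SeriesPolicy) -> float:
    """Term-wise derivative: differentiate the ascending factorials."""
    x = args["x"]
    a = args.get("a")
    b = args.get("b")
    c = args.get("c")
    total = 0.0
    term = 1.0  # series term value at k
    small = 0
    for k in range(policy.max_terms):
        if k > 0:
            if kind.startswith("f11"):
                term *= (a + k - 1) / (b + k - 1) * x / k
            else:
                term *= (a + k - 1) * (b + k - 1) / (c + k - 1) * x / k
        w = _poch_ratio_terms(kind, args, k)
        t = term * w
        total += t
        if k > 0 and abs(t) <= policy.threshold(total) and abs(term) <= policy.threshold(total):
            small += 1
            if small >= policy.consecutive_small:
                return total
        else:
            small = 0
    raise SeriesError(f"term-wise {kind} derivative did not converge")


def dhyp_param(kind: str, base_args: dict,
               series_policy: SeriesPolicy = DEFAULT_SERIES,
               deriv_policy: DerivPolicy = DEFAULT_DERIV,
               warnings: list | None = None) -> float:
    """Derivative of 1F1/2F1/Appell F1 with respect to one parameter slot.

    ``kind`` is one of ``f11_a``, ``f11_b``, ``f21_a``, ``f21_b``, ``f21_c``,
    ``appell_slot``.  ``base_args`` holds the base parameters (``a``, ``b``,
    ``c`` for 2F1, plus ``x``; for ``appell_slot`` the Appell arguments and
    ``slot`` a callable).  Evaluated term-wise (digamma-weighted series) and
    by central differences; the term-wise value is returned and a warning is
    attached when the routes disagree beyond 1e-6 relative.
    """
    if kind == "appell_slot":
        f = base_args["slot"]
        return param_derivative(f, 0.0, deriv_policy, warnings)

    if kind.startswith("f11"):
        fd_f = lambda eps: _perturbed_f11(kind, base_args, eps)
    else:
        fd_f = lambda eps: _perturbed_f21(kind, base_args, eps)
    fd = param_derivative(fd_f, 0.0, deriv_policy)
    try:
        tw = _hyp_termwise(kind, base_args, series_policy)
    except SeriesError:
        if warnings is not None:
            warnings.append(f"{kind}: term-wise route failed; finite differences used")
        return fd
    if abs(tw - fd) > 1e-6 * max(1.0, abs(tw)) and warnings is not None:
        warnings.append(
            f"{kind}: term-wise ({tw:.10g}) and finite-difference ({fd:.10g}) "
            "routes disagree beyond 1e-6 relative"
        )
    return tw


def _perturbed_f11(kind: str, args: dict, eps: float) -> float:
    a, b, x = args["a"], args["b"], args["x"]
    if kind == "f11_a":
        return sp.hyp1f1(a + eps, b, x)
    return sp.hyp1f1(a, b + eps, x)


def _perturbed_f21(kind: str, args: dict, eps: float) -> float:
    a, b, c, x = args["a"], args["b"], args["c"], args["x"]
    if kind == "f21_a":
        return sp.hyp2f1(a + eps, b, c, x)
    if kind == "f21_b":
        return sp.hyp2f1(a, b + eps, c, x)
    return sp.hyp2f1(a, b, c + eps, x)


# --- incomplete beta parameter derivatives (J-shaped row) -------------------

def incbeta(x: float, a: float, b: float) -> float:
    """Lower incomplete beta ``B_x(a,b)`` (unregularized)."""
    return sp.betainc(a, b, x) * math.exp(sp.betaln(a, b))


def dincbeta_first(x: float, a: float, b: float,
                   policy: DerivPolicy = DEFAULT_DERIV) -> float:
    """``d B_x(a,b) / da`` by Richardson central differences."""
    return param_derivative(lambda e: incbeta(x, a + e, b), 0.0, policy)


def dincbeta_second(x: float, a: float, b: float,
                    policy: DerivPolicy = DEFAULT_DERIV) -> float:
    """``d B_x(a,b) / db``."""
    return param_derivative(lambda e: incbeta(x, a, b + e), 0.0, policy)
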