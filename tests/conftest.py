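import math

import pytest
from scipy import integrate


def integrate_density(fam, values, rel_tol: float = 1e-11) -> float:
    """Numeric integral of a registry density over its support.

    Infinite panels are integrated in log-space so heavy power-law tails
    are not lost; finite supports use a mid-split.
    """
    lo, hi = fam.support(values)

    def f(x: float) -> float:
        return fam.pdf(values, x)

    if math.isfinite(lo) and math.isfinite(hi):
        mid = 0.5 * (lo + hi)
        a1, _ = integrate.quad(f, lo, mid, epsrel=rel_tol, limit=300)
        a2, _ = integrate.quad(f, mid, hi, epsrel=rel_tol, limit=300)
        return a1 + a2

    def tail(edge: float, sgn: float) -> float:
        def g(u: float) -> float:
            try:
                eu = math.exp(u)
            except OverflowError:
                return 0.0
            if math.isinf(eu):
                return 0.0
            return f(edge + sgn * eu) * eu

        edges = [-700, -30, -10, -3, 0, 3, 10, 30, 700]
        total = 0.0
        for a, b in zip(edges[:-1], edges[1:]):
            v, _ = integrate.quad(g, a, b, epsrel=rel_tol, limit=300)
            total += v
        return total

    if math.isfinite(lo):
        return tail(lo, 1.0)
    if math.isfinite(hi):
        return tail(hi, -1.0)
    v, _ = integrate.quad(f, -math.inf, 0.0, epsrel=rel_tol, limit=300)
    w, _ = integrate.quad(f, 0.0, math.inf, epsrel=rel_tol, limit=300)
    return v + w


@pytest.fixture(scope="session")
def fixture_pairs():
    """Cache of the per-family fixture pair grids used across tests."""
    from klexact.fixtures import pair_grid

    cache: dict[tuple[str, int], list] = {}

    def get(family: str, n: int = 20):
        key = (family, n)
        if key not in cache:
            cache[key] = pair_grid(family, n)
        return cache[key]

    return get
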