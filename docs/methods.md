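# Methods

## What is computed

For two densities `f1`, `f2` of the *same* parametric family, the
Kullback–Leibler divergence

    KLD(f1 ‖ f2) = ∫ f1(x) [log f1(x) − log f2(x)] dx

has an exact closed form in terms of elementary and special functions for
each of the 61 continuous univariate families in the registry.  `klexact`
implements those expressions (`klexact.kld`), an independent evaluation of
the defining integral by adaptive quadrature (`klexact.kld_numeric`), and a
harness that compares the two over parameter grids (`klexact.verify`).

The orientation is fixed: the expectation is always under the first
density.  The measure is asymmetric, and orientation mix-ups are the
dominant user error, so the CLI prints the orientation with every result.
Units are nats (natural logarithm); `--bits` divides by `log 2`.

## Parameterizations

Each family is stored exactly in the parameterization its closed form was
derived in — e.g. the exponential is indexed by its rate, the Rayleigh
density is `2b²x·exp(−(bx)²)`, the Weibull uses `(bx)^a` so `b` is an
inverse scale, and the inverse Gaussian carries (shape, mean).  A
conversion layer to "standard" parameterizations was deliberately not
added: silent sign/scale conversions are the easiest way to corrupt a
divergence formula, and within-family comparisons never need them.
`families.json` (regenerable via `klexact.families_json()`) documents every
schema.

Two printed source densities required normalization corrections, flagged in
the registry and in `klexact.ERRATA`:

* **half-normal** — the printed density lacks the `1/√π` factor;
* **half-logistic** — the printed density does not integrate to one for any
  shape except 1; the registry uses the type-I generalized half-logistic
  density `a·2^a e^{−ax}(1+e^{−x})^{−(a+1)}`, whose divergence reduces to
  `log(a/b)+b/a−1` (confirmed by quadrature).

Such corrections never change a divergence value, because normalizing
constants cancel between the two densities of a within-family pair — the
oracle agreement tests confirm this.

## Evaluation strategies

Expressions are grouped by how they are evaluated, and each result reports
its route in `KLDResult.method`:

* **closed_elementary** — elementary/digamma/erf/Bessel-ratio expressions,
  evaluated directly (gamma, normal, beta, truncated normal, harmonic, …).
* **closed_derivative** — rows whose tabulated form contains a parameter
  derivative `∂/∂α[·]|₀`.  Wherever a standard reduction exists (Weibull,
  Fréchet, Nakagami, Pareto I, Burr, generalized gamma: derivatives of
  `b^{−α}Γ(c+α)` and of beta functions reduce to digammas and `log` terms)
  the reduction is implemented and the numerical-derivative route is kept
  as a test oracle.  Where no reduction exists (hypergeometric parameter
  slots), Richardson-extrapolated central differences are used with a
  term-wise digamma-series cross-check.
* **closed_series** — rows with infinite sums (beta exponential, Cauchy,
  Student's t, F, Lomax-type, omega, …), summed under a `SeriesPolicy`
  (stop after 3 consecutive terms below `max(abs_tol, rel_tol·|sum|)`,
  default `1e−15`/`1e−12`, budget 100 000 terms).  Sums with power-law
  term decay `k^(−1−c)` (beta-function tails) are finished with an
  Euler–Maclaurin tail estimate instead of brute-force summation.
* **closed_specialfn** — the four beta-like families whose expressions
  differentiate `1F1`/`2F1`/Appell `F1` with respect to a parameter slot
  (confluent and Gauss hypergeometric beta, Libby–Novick beta) and the
  generalized Pareto.

### Series convergence guards and the oracle fallback

`convergence_guard(family, p1, p2)` checks, before evaluation, that every
series argument lies inside its radius of convergence:

* Cauchy / half-Cauchy: `|1 − r²/σ²| < 1`;
* Student's t / half-Student's t: `|1 − p r²/(n σ²)| < 1`;
* gamma-Gompertz: `|e − 1| < 1` for the second shape;
* Gauss hypergeometric beta / Libby–Novick beta: the Appell `F1`
  arguments must satisfy `|x|,|y| < 1`;
* Burr and generalized beta II with *different* shape exponents between
  the two densities: see below.

Outside these domains `kld` evaluates the defining integral instead and
flags the result `oracle_fallback`, with the guard named in `warnings`.

The Burr and GB2 cross-shape series deserve a note: expanding
`log(1+w·U^ρ)` term-by-term requires moments `E[U^{kρ}]` that cease to
exist beyond order `c·b/e`, so the tabulated series is only *asymptotic*
in `w = (d/a)^e`, with an error floor of order `w^{cb/e}` that no
truncation can beat.  The implementation uses the optimally truncated
series only when that floor is below `1e−10` and otherwise routes to the
oracle.  When the shape exponents match, the term is computed exactly
through a convergent Gauss-hypergeometric representation instead, so
matched-shape calls never fall back.

### Derivative operators

Every `∂/∂α|₀` device has two routes: term-wise differentiation of the
hypergeometric series (ascending factorials differentiate to digamma
sums) and Richardson-extrapolated central differences; the routes are
compared at `1e−6` relative and disagreement attaches a warning.  The
default finite-difference step is `eps^{1/(2L+3)}·max(1,|α₀|)` for `L`
Richardson levels (so `eps^{1/7} ≈ 5·10⁻³` at the default `L = 2`): this
balances the `O(h^{2L+2})` truncation against roundoff, whereas the
classic `eps^{1/3}` step — optimal for a bare central difference — would
leave roundoff dominant after extrapolation and miss the `1e−10`
polynomial-exactness property.  For the Appell-slot derivatives the double
series is first summed to near roundoff (`rel_tol 1e−15`), since
differencing amplifies series truncation noise by `1/h`.

The Bessel order derivative `∂K_ν(x)/∂ν` (generalized inverse Gaussian
row) is evaluated by `mpmath` numerical differentiation at 30 significant
digits; it is odd in `ν` and exactly zero at `ν = 0`.

### Re-derived rows

Several tabulated expressions reached this project garbled (typesetting
slips and lossy extraction).  Rather than guess at symbols, those rows
were re-derived from the printed densities and adjudicated against the
quadrature oracle, which is the correctness criterion the original
verification protocol itself uses.  They are: continuous Bernoulli,
asymmetric Laplace (both densities share the location `c`; the divergence
is location-free), exponentiated exponential (second-density exponent
`b−1` is a typo for `c−1`; the literal printed form is preserved as
`kld_paper_verbatim` and demonstrably disagrees with the integral),
gamma-Gompertz, transmuted exponential, and omega.  `klexact.ERRATA`
carries one entry per corrected row.  Some re-derived forms are *simpler*
than the printed ones: the J-shaped, half-logistic and Pareto I rows all
collapse to `log(a/b)+b/a−1` (for Pareto I the printed derivative device
is implemented literally and reduces to the same value; for J-shaped the
collapse follows from `(X(2−X))^a` being uniform under `f1`).

Derivations used throughout: the logarithmic expansions
`log(1−e^{−αx}) = −Σ e^{−kαx}/k` and `log(1+z) = Σ(−1)^{k−1}z^k/k`, the
moment-derivative device `E[log X] = d/dα E[X^α]|₀`, and for the
`t`-family the representation `X²/(nσ²) ~ BetaPrime(1/2, n/2)`.  The
`E[log(1−zV)]`, `V ~ Beta(α,β)` building block is summed in whichever of
its two geometric-rate expansions (around `V` or around `1−V`) applies,
which jointly cover every admissible scale ratio for the F family and for
matched-shape GB2; the analogous Cauchy/Student-t series follow the
tabulated form with prefactor `c^{1/2}` and argument `1−c` and were
verified against the elementary Cauchy value `log((σ+r)²/(4σr))`.

## The quadrature oracle

`kld_numeric` integrates `f1·(log f1 − log f2)` built from log-densities
(never the density ratio — tails overflow).  The support is split at the
bulk of the integrand (mode search on a probe grid; decade breakpoints for
semi-infinite supports), Laplace-type kinks are added as breakpoints, and
every infinite panel is integrated after the substitution `x = edge ± e^u`,
which turns power-law tails into exponentially decaying integrands.  This
last point matters: the plain infinite-interval transform silently loses
an `O(10⁻²)` tail contribution for the heaviest-tailed fixtures (inverse
chi-square with half a degree of freedom) *while reporting* a `10⁻¹²`
error estimate.  Endpoint singularities (beta-type densities with shape
< 1) are never evaluated at the endpoint; the integrand is defined as 0
wherever `f1` vanishes or underflows.  Cross-family calls are supported,
and a support violation returns `+inf` with a warning rather than raising.

## Verification protocol

`run_paper_grids()` reproduces the published correctness check: chi,
exponential, generalized logistic type I and power function type I, one
parameter fixed at 1, the other swept over the integers 1…100, in both
orientations — 800 grid points, each comparing the closed form against the
oracle.  The published figures only show that the differences are
negligible on the figure axes; the pass bar used here, `max |closed −
oracle| ≤ 1e−6` per report, is this package's own (conservative) choice.
Measured maxima are near `1e−12`.

The generalized check (`scripts/acceptance.py`, `tests/test_acceptance.py`)
extends oracle agreement to all 61 families over the deterministic fixture
grids in `klexact.fixtures` (20 admissible pairs per family, parameter
pools spanning shapes/scales in roughly (0.5, 3), filtered through the
convergence guards), at tolerance `max(1e−5, 1e−5·|value|)`.  Fixture
sizes were chosen so the whole suite runs in well under a minute on one
CPU; the observed agreement (≈`3·10⁻⁹` worst case) is limited by the
oracle, not the closed forms.

## Numerical choices and degenerate inputs

* `q`-exponential: `a = 1` (and/or `c = 1`) is the exponential limit; the
  printed `1/(1−a)` terms are singular there, so the limit is taken
  analytically (the family is a reparameterized Lomax for `a > 1`; the
  divergence against an exponential requires `a < 1.5` for a finite mean
  and returns `+inf` otherwise).
* Truncated normal: `L = −∞` or `U = +∞` are accepted; `φ`/`Φ` terms at
  infinite endpoints take their limits (0).  `(L, U)` must match between
  the two densities, as must every shared parameter (Pareto I threshold
  `K`, generalized uniform `(a, b)`, asymmetric Laplace and omega
  locations).
* Continuous Bernoulli: the normalizer `2·atanh(1−2a)/(1−2a)` and the mean
  have removable singularities at `a = 1/2`, handled by series expansion
  below `|1−2a| < 10⁻⁵`.
* Density endpoints are open unless the table states otherwise; `pdf` at a
  finite endpoint returns the continuous limit when finite, else 0, and
  `pdf` outside the support returns 0 rather than raising.
* Gibbs' inequality is allowed `−1e−8` slack for roundoff; series results
  additionally carry `truncation_bound` (heuristic: last included term ×
  stopping run length — not a rigorous bound).

## Limitations

* Closed forms are within-family only; cross-family divergences are
  available solely through the oracle.
* The convergence guards are conservative where the printed series is
  asymptotic (Burr/GB2 cross-shape); those parameter regions are served by
  quadrature and are excluded from closed-form agreement statements.
* `mpmath` is used for the Bessel order derivative and as an overflow
  fallback for extreme hypergeometric arguments; extreme parameter values
  (far outside the fixture pools, e.g. shape ratios of 10³) may be slow or
  trip series budgets.
* Random variate generation, CDFs/quantiles and fitting are out of scope;
  the registry densities exist to serve the divergence computations.
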