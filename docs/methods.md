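# Methods

## Model

An individual with resource budget (quality) R chooses investments
u₁, …, uₙ ≥ 0, Σuᵢ = R, in positive-valued, increasing fitness components
xᵢ(uᵢ).  Fitness is W = Σxᵢ (additive) or W = Πxᵢ (multiplicative).  The
package computes global maximizers of W on the budget simplex, traces them
over budget grids, and classifies the resulting signal-investment path
u₁*(R) as honest (non-decreasing) or not.

Interior optima satisfy marginal-return equalization: equal slopes xᵢ′
under additive fitness, equal elasticities Sᵢ = xᵢ′/xᵢ under multiplicative
fitness; a funded/unfunded pair must satisfy Sᵢ(uᵢ*) ≥ Sⱼ(0).  These
first-order conditions are *verified*, never used as the solver — the
solver is a global direct search, so multimodal objectives and corner
optima are handled uniformly.

Two analytic diagnostics on the viability component x₂ frame the honesty
question.  The margin m(u) = x₂″x₂ − (x₂′)² has the sign of S₂′ wherever
x₂, x₂′ > 0: m > 0 somewhere is necessary (not sufficient) for honesty to
break down, and is impossible for linear or decelerating viability
(m = −(x₂′)² + x₂″x₂ < 0 when x₂″ ≤ 0).  Conversely, S₂ strictly
decreasing over the visited investments is sufficient for honesty; the
package treats a dishonest path together with strictly decreasing S₂ as an
internal error (a non-global optimum slipped through) and raises rather
than reporting it.

The signal trait itself is not modelled: it is assumed monotone in u₁, so
honesty is defined directly on u₁*(R).

## Solver

For n = 2 the problem is one-dimensional in u₁ ∈ [0, R].  A dense uniform
scan (default 4096 points) brackets every local maximum; each bracket is
polished by bounded scalar minimization (Brent, |Δu| ≤ 1e−10); both
endpoints are always candidates.  A single-start local method would be
wrong here: the threshold scenario's objective is bimodal over a range of
budgets, and the global optimum hops between branches, which is exactly
what produces the discontinuity in u₁*(R).  Ties within 1e−9 in W return
the smallest-u₁ optimum and set `multiplicity` — the discontinuity budget
is the tie point, so deterministic tie-breaking makes paths reproducible.

For n > 2 a seeded multistart SLSQP (default 16 Dirichlet starts plus the
barycenter and corners) is provided as best-effort; the brute-force
simplex grid (`brute_force_allocation`) is the independent oracle for
small n, and is used as such throughout the tests.

Budget conservation is enforced exactly (rescaling u so Σu = R);
investments below 1e−12 are snapped to 0 and flagged as corners.

Path discontinuities are flagged where |Δu₁*| between adjacent grid points
exceeds max(0.05, 10 × median adjacent |Δu₁*|), then refined by bisection
on R — re-solving at the midpoint and keeping the half containing the jump
— to a bracket of width ≤ 1e−4.

## Component catalog and derivatives

Catalog forms (linear, quadratic, affine-quadratic, power-sum, exp-erf,
double-exponential, exponential) carry analytic first and second
derivatives; tests check them against both central finite differences and
independent symbolic differentiation.  User-tabulated components are
interpolated with a cubic spline and differentiated by central differences
with step h = 1e−6·max(1, |u|) (one-sided at the domain edge); at that
step, second differences are roundoff-limited to ~1e−4 relative accuracy,
which is accepted as the contract for tabulated input.  Positivity of
components under multiplicative fitness is checked and *reported*
(`TradeoffScenario.check_positivity`), never silently clipped.

## Honesty report

Monotonicity of u₁*(R) is assessed with an absolute tolerance (default
1e−6 in u₁) so refinement noise cannot create spurious dishonesty.  A
corner prefix (u₁* = 0 at low budgets) is reported separately and does not
count as dishonest — an absent signal just marks the lower quality range.
The flat-signal case of the additive trade-off (x₁* constant) is likewise
distinguished from dishonesty via the `x1_flat` field: no violation
intervals, but max−min of x₁* below tolerance, i.e. the signal is
uninformative rather than misleading.  S₂ monotonicity is probed at 512
uniform points (descending with margin > 1e−12) — a necessary-condition
check, not a proof; condition-8 regimes are located by probing plus Brent
root bracketing, with |m| below 1e−9 relative to (x₂′)² classified as the
exponential knife-edge (m ≡ 0 for x = c·e^{ku}).

## Geometry

Phenotype sets are the parametric curves {(x₁(u₁), x₂(R−u₁))}, sampled at
256 points by default.  Isoclines are x₂ = W − x₁ (additive) or x₂ = W/x₁
(multiplicative).  The optimal locus strings the per-budget optima
together; discontinuities are encoded as explicit NaN break rows (listed
in `meta["gaps"]`), never interpolated, so a jump is drawn as a gap rather
than a connecting segment.  Tangency of the phenotype set with the
W*-isocline is checked via the normalized cross product of the two tangent
directions and is inapplicable (raises, distinct from False) at corners.

## Random-scenario generator

The generator emulates the study conditions for the property claims, not
empirical data (none exists for this model).  It draws multiplicative
two-component scenarios with a mating component that is strictly positive
and strictly increasing on the working range u ∈ [0, 10] *by construction*
(concave quadratic with intercept in [0.1, 1], slope in [0.5, 2], curvature
bounded so the slope stays positive) — no clipping.  Viability comes from
a requested curvature class: decelerating (concave quadratic with positive
intercept, hence S₂ strictly decreasing), linear (positive slope and
intercept, m = −slope² < 0), or accelerating (a·u + b·u^k, k ∈ [8, 20]).
Scenarios with accelerating viability carry a recommended budget range of
[0, 3], where the steep power keeps values in comfortable floating-point
range while still reaching the dishonest regime.  The same seed always
yields the same scenario.

What passing property tests show: the solver matches an exhaustive grid
oracle, elasticities equalize at interior optima, decreasing S₂ scenarios
are always classified honest, and every detected violation co-occurs with
a condition-8-positive interval.  What they do not show: anything about
receiver behavior, signal-trait mechanics, heritability, or allocation
flexibility over a lifetime — all outside the model.

## Problem sizes and defaults

Worked-scenario paths use 150–600 budget grid points (600 with a
4096-point scan per budget for the threshold scenario's checkpoints —
about one second); property tests use 512–1024-point scans, which suffice
for the smooth generated scenarios, against 10⁴-point oracle grids.
Floating-point output is printed with 10 significant digits; identical
invocations with identical seeds are byte-identical.

## Known limitations

- n > 2 optimization is local-multistart, not exhaustive; use the oracle
  for verification at small n.
- Honesty classification is grid-based: a violation narrower than the
  budget grid spacing can be missed, and probed S₂ monotonicity is
  evidence, not proof.
- Direct viability costs of signaling (beyond resource diversion) and
  receiver/preference coevolution are not modelled.
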