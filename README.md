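# balancemodel

Tools for the **balance model** of honest sexual signaling: why do costly
ornaments reliably indicate quality, without invoking "waste"?  The package
treats signaling as a resource-allocation problem.  An individual of quality
*R* (its total resource budget) splits investments *u₁, …, uₙ ≥ 0* with
*Σuᵢ = R* among positive, increasing fitness components *xᵢ(uᵢ)* — typically
mating success *x₁* and viability *x₂* — and fitness combines them either

- **additively**: `W = x₁ + x₂ + … + xₙ`, or
- **multiplicatively**: `W = x₁ · x₂ · … · xₙ`.

At an interior optimum, the marginal fitness return on every funded
component must be equal.  Under additive fitness this equalizes the slopes
`xᵢ′(uᵢ*)`; under multiplicative fitness it equalizes the **elasticities**
(selection gradients)

```
Sᵢ(uᵢ) = xᵢ′(uᵢ) / xᵢ(uᵢ),      Sᵢ(uᵢ*) = Sⱼ(uⱼ*),
```

with the corner rule `Sᵢ(uᵢ*) ≥ Sⱼ(0)` for unfunded components *j*.
Signaling is **honest** when optimal signal investment *u₁\*(R)* never
decreases in *R*: bigger signals then imply higher quality.  Honesty is
guaranteed whenever *S₂* is strictly decreasing; it can only break down if
the viability margin

```
m(u₂) = x₂″(u₂)·x₂(u₂) − x₂′(u₂)²
```

turns positive somewhere (viability accelerating strongly enough that its
elasticity rises with investment) — a necessary, not sufficient, condition.

The package provides:

- a catalog of component functions with analytic derivatives, elasticities
  and the margin *m(u)* (`balancemodel.components`),
- a global solver for the budget-constrained allocation problem, allocation
  paths over budget grids, discontinuity detection with bisection
  refinement, and first-order-condition verification
  (`balancemodel.optimize`),
- honesty reports with violation intervals, corner prefixes and the
  analytic conditions on viability (`balancemodel.honesty`),
- fitness-set geometry: phenotype sets, fitness isoclines, optimal loci and
  tangency checks (`balancemodel.geometry`),
- built-in worked scenarios plus a seeded random-scenario generator
  (`balancemodel.scenarios`), and a CLI (`balancemodel`).

It is aimed at theoreticians in sexual selection / life-history evolution
who want to explore allocation trade-offs, and at anyone needing a small,
well-tested global 1-D allocation optimizer with honesty diagnostics.

## Worked example

The additive worked scenario (mating success `x₁ = 1.5u₁ − 0.7u₁²`,
viability `x₂ = u₂`) pins the signal at the unique slope-matching point
`1.5 − 1.4u₁ = 1`, i.e. `u₁* = 5/14 ≈ 0.357`, `x₁* ≈ 0.446` — regardless of
quality, so the signal carries no information.  The multiplicative version
of the same trade-off is honest:

```bash
$ balancemodel optimize --scenario fig1_multiplicative --R 1.0
{
  "scenario": "fig1_multiplicative",
  "rule": "multiplicative",
  "R": 1.0,
  "u": [0.4285714295, 0.5714285705],
  "x": [0.5142857151, 0.5714285705],
  "W": 0.293877551,
  ...
  "gradient_residual": 7.915308631e-09,
  ...
}
```

`u` is the optimal split of `R = 1` (u₁* = 3/7 exactly, from the
first-order condition 2.1u² − 4.4u + 1.5 = 0), `x` the component values,
and `gradient_residual` the elasticity mismatch |S₁ − S₂| at the optimum —
here ~10⁻⁸, confirming elasticity equalization.

The threshold scenario (`fig3`: `x₁ = exp[0.1u₁ + erf(3(u₁−3))]`,
`x₂ = exp[1 − exp(−u₂)]`) shows honesty surviving a rich allocation
pattern:

```bash
$ balancemodel honesty --scenario fig3 --rmin 0 --rmax 6 --steps 200
{
  "honest": true,
  "violation_intervals": [],
  "corner_prefix": [0.0, 2.291457286],
  "condition8_positive_intervals": [],
  "s2_strictly_decreasing": true,
  ...
  "discontinuities": [[2.89941897, 2.899477858]]
}
```

Low-quality individuals do not signal at all (`corner_prefix`: u₁* = 0 up
to R ≈ 2.3 — uninformative, not dishonest), the optimal allocation then
jumps discontinuously at R ≈ 2.9 (`discontinuities`, bracket refined to
width ≤ 10⁻⁴), yet u₁*(R) never decreases: signaling stays honest, as the
strictly decreasing viability elasticity S₂(u₂) = e^(−u₂) guarantees.

Other entry points: `balancemodel path … > CSV` for allocation paths,
`balancemodel figure fig1_multiplicative` for phenotype-set / isocline /
optimal-locus CSV bundles (add `--plot` for a PNG), `list-scenarios` for
the catalog.  Custom scenarios go in a YAML config:

```yaml
rule: multiplicative
components:
  - {form: quadratic, params: {a: 1.5, b: 0.7}, name: mating success}
  - {form: linear, params: {slope: 1.0}, name: viability}
```

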