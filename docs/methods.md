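# Methods

## Model

The package prices life extension through a life-cycle expected-utility
model. At age `a`, under quality-of-life (QoL) scenario `m`, the value of a
statistical life is

    VSL_m(a) = ∫_a^∞ D(t,a) ( y^F(t) + Φ_m(z_m(t)) c^F(t) ) S(t,a) dt

with `D(t,a)` the discount kernel, `S(t,a)` conditional survival, `y^F` full
income and `c^F` full consumption (Murphy–Topel-style constructs that bundle
market flows with the value of non-market time, carried internally in
million JPY per year). The elasticity weight

    Φ(z) = u(z) / (z u'(z)) − 1

converts the utility of the composite consumption–leisure good `z` into a
money-equivalent weight on full consumption. QoL enters by scaling the
composite good, `z_m(t) = H_m(t) c^F(t)`: poorer health lowers the enjoyable
value of the same consumption flow, hence Φ, hence the consumption term of
the integrand. The life-extension value replaces `S(t,a)` with the
unit-area survival increment `S(t−1,a) − S(t,a)` (the effect of shifting the
survival curve by one year), and the monetary value of one QALY divides it
by current QoL:

    QALY_m(a) = LEV_m(a) / H_m(a).

Policy impact compares the conventional flat benchmark `QALY_base`
(5 million JPY) with the scenario-mixed, age-specific values over the adult
population:

    Cost Reduction = Σ_a N_a ( QALY_base − Σ_m β_m QALY_m(a) )   [trillion JPY].

### Assumptions

- Survival is scenario-independent; scenarios alter only the QoL path. The
  equal-area construction (below) holds the *total* life-extension effect
  fixed across scenarios, isolating the timing of health decline.
- Utility is state-separable in the composite good; health affects utility
  only through the multiplicative coupling `z = H·c^F`. The coupling rule is
  pluggable (`PreferenceModel.coupling`), multiplicative being the simplest
  rule consistent with `H ∈ [0,1]` scaling the enjoyment of the bundle.
- Φ is floored at −1 everywhere, so the integrand's consumption term is
  never below `−c^F` and the `H → 0` limit is bounded: past a scenario's
  terminal age the flow is `y^F − c^F`. This floor is what makes early
  truncation costly and is the mechanism behind the slow-decline scenario
  having the *lowest* QALY price at every age: its early terminal age puts
  `−c^F` years where other scenarios still enjoy positive flows.

## Parameters

| parameter | default | units | meaning |
|---|---|---|---|
| `r` | 0.01 | /year | interest rate of the exponential kernel |
| `κ` | 0.01 | /year | hyperbolic kernel `1/(1+κ(t−a))` (variant) |
| utility | `log` | — | baseline `u(z)=ln z`; CRRA `(z^{1−η}−1)/(1−η)` variant |
| `η` | 0.8 | — | CRRA curvature when the CRRA variant is selected |
| `z0` | calibrated | M JPY/yr | reference scale of the composite good |
| `QALY_base` | 5.0 | M JPY | conventional benchmark price of one QALY |
| `A_max` | 110 | years | truncation of the model's infinite horizon |
| SCN4 shock | 0.75 | QoL | post-shock level at age 60 |
| anchor age | 0 | years | age at which "total VSL" is reported |

Logarithmic utility is the baseline rather than a curved CRRA: it is the
η→1 limit of the CRRA family, it is the standard benchmark case in the
value-of-life literature, and under it the scenario-relative part of the
integrand, `ΔΦ = Δ ln H`, is invariant to both the money scale and `z0`,
which makes the scenario comparisons transparent. The CRRA variant (any
η ≥ 0, η ≠ 1) and the hyperbolic kernel are exposed for sensitivity
analysis; on the shipped inputs the *ordering* of scenario results is
unchanged under either (the CRRA-η=0.5 variant keeps the baseline-calibrated
`z0`, since its Φ is bounded above by 1 and cannot reach the VSL
calibration target on its own).

### Calibration of z0

The model inherits its consumption-utility calibration from the
value-of-life literature rather than estimating it from microdata. The one
free scale, `z0`, is solved once per dataset (Brent's method on log z0) so
that the baseline scenario's total VSL — `VSL(a₀)` at the anchor age,
default 0 — equals a configurable benchmark, by default 457.6 million JPY,
a published Japanese VSL estimate. Φ is strictly decreasing in `z0`
pointwise, so the calibrated root is unique. After calibration, every
scenario difference, every LEV and QALY curve and every policy number is a
genuine model output. The alternative "total VSL" reading — the sum of
VSL-years from age 20 — is exposed as `ValuationResult.vsl_year_sum`.

## QoL scenarios and the equal-area constraint

Scenario specs are declarative: ordered `(start_age, annual_rate)` segments
(a zero rate encodes a plateau), an optional `(age, level)` shock, and a
decline mode. Multiplicative decline (`H ← H(1−rate)`) is the default;
linear decline is retained as an option, with the caveat that a linear SCN2
truncated to SCN1's area reaches zero QoL at ≈79.3 years, which contradicts
reported finite QALY values at age 80 — one reason multiplicative is the
default. The built-ins:

- SCN1: −2 %/yr after 50 (reference; never truncated).
- SCN2: −1 %/yr after 50.
- SCN3: −1 %/yr from 30, plateau 50–70, −1 %/yr after 70.
- SCN4: drop to 0.75 at 60, then −1 %/yr.

SCN2–SCN4 are truncated at a solved terminal age so their lifetime QoL area
(trapezoidal integral of the piecewise-linear interpolant of H over
`[0, A_max]`, evaluated exactly at fractional truncation ages) matches
SCN1's to 1e-6 QoL-years. The truncated area is continuous and
non-decreasing in the truncation age, so bisection (Brent) is guaranteed to
converge; a spec whose untruncated area is below the target raises an
infeasibility error reporting both areas. Under multiplicative decline with
`A_max = 110` the SCN4 shock level must exceed ≈0.64 for the constraint to
be feasible; the default 0.75 is a large-but-partial drop comfortably inside
the feasible region. Area accounting starts at age 0; since every scenario
has `H = 1` through childhood, the solver is invariant to that choice of
lower bound.

## Numerics

- Age grid: integer years 0..110. Japanese complete life tables end near
  110 and survival beyond is negligible; the infinite upper limits are
  truncated there.
- Quadrature: composite trapezoid on the unit grid — the inputs are annual,
  so higher-order schemes add nothing. An optional refinement factor
  interpolates the inputs (not the integrand product) onto a finer grid;
  halving the step moves VSL and LEV by < 0.05 % on the shipped preset.
- `l(x)` is interpolated linearly between integer ages; `S(t,a) = l(t)/l(a)`,
  0 beyond the table and wherever `l(a) = 0`.
- The LEV grid extends one year past `A_max` so the final survival increment
  is fully captured; `S(t−1,a)` is 1 for `t−1 ≤ a` (one cannot have died
  before the conditioning age). In the `r = 0`, `H ≡ 1`, constant-flow limit
  this makes LEV equal the flow *exactly* whenever survival has vanished by
  `A_max` — the unit-area property used as an oracle in the tests.
- `QALY_m(a)` at ages with `H_m(a) = 0` is undefined and raises, never
  silently skipped; curve containers carry a support mask instead.
- Population weighting and the policy sum run over adult ages (20+) with
  positive population, intersected with the support of every
  positively-weighted scenario; the published national shortfall figures are
  arithmetically consistent with an adult-population sum, not an all-ages
  sum, which fixed this otherwise-open convention.
- Proportion vectors are accepted in percent and normalised; rounding
  happens only at presentation.
- Equality tolerances: 1e-12 relative for discrete-sum oracles, 1e-6
  QoL-years for the area solver, 1e-9 relative for affine identities.

## The synthetic japan-like preset

The real inputs are public aggregate statistics (complete life tables, the
wage-structure and household-consumption surveys, population by single year
of age). Nothing here downloads them; instead `synthdata` generates
deterministic stand-ins with their statistical shape, and the preset's
defaults are the package's study conditions:

- **Mortality**: Gompertz–Makeham hazard `μ(x) = 2e-4 + 2.5e-6·e^{0.117x}`,
  giving life expectancy ≈ 86, survival to 90 of ≈ 0.44 and `l(110) ≈
  2e-4` — a long-lived population with substantial survival mass past 90,
  as in recent Japanese tables. That late mass matters scientifically: it
  is what makes early QoL truncation expensive in the LEV and hence
  separates the scenarios' QALY prices.
- **Full income**: gamma-shaped hump from labour-market entry (18) peaking
  at 47, tapering smoothly to zero across retirement (60–75).
- **Full consumption**: base 2.5 with a mid-life bump around the
  peak-earnings years (reaching ≈ 4.1 at 50) and a rise at very old ages —
  full consumption includes the imputed value of non-market time, which
  dominates the bundle in late retirement, so unlike market spending it
  does not decline with age.
- **Pyramid**: mixture of cohort bumps (young, mid-career boom, old-age
  boom) damped by survival, normalised to 125 million people; a stylised
  super-aged population (mean age ≈ 57) in which the old-age cohorts carry
  most of the policy weight.
- The curves are deterministic given parameters; the seed drives only
  optional multiplicative noise used to exercise the CSV readers.

What the preset does *not* emulate: sampling error and survey artefacts in
the real tables, cohort (period-vs-generation) effects, household-size
adjustments, sex-specific mortality, and the actual Murphy–Topel Φ
trajectory for Japan, which is not published. Consequently, passing tests
demonstrate the *mechanisms* — scenario orderings, age gradients, the sign
flip of the policy balance as healthy life expectancy spreads — not the
published point values; with real inputs the levels would shift while the
comparative statics are the model's own.

## Design choices that were genuinely open

- **Baseline utility form.** The source framework calibrates Φ following the
  value-of-life literature without printing the trajectory or the utility
  form. Under curved CRRA baselines (η ≤ 1) the equal-area construction
  rewards scenarios that move QoL mass from near-worthless very old ages
  into well-survived ages, inverting the expected scenario ordering on
  generic inputs; the log baseline (with the Φ floor at −1) reproduces the
  documented comparative statics and is the transparent η→1 limit. CRRA is
  a first-class variant.
- **Decline semantics.** "Decreases by k% annually" is read as relative
  (multiplicative) decline by default; linear absolute decline is a config
  option, fully tested.
- **SCN4 shock depth** is not published; 0.75 is the default (feasibility
  requires > ~0.64 under the defaults) and it is a config knob.
- **Total VSL anchor.** "The sum of all VSL-years" does not pin the age at
  which the total is read; the package reports `VSL(0)` and exposes the
  from-age-20 sum alongside.
- **Age range of the policy sum**: adults (20+), per the arithmetic
  consistency argument above; configurable.

## Limitations

- Exact reproduction of published national point values requires the actual
  government tables and the unpublished Φ calibration; this package ships
  the machinery plus a synthetic preset, not the data.
- Consumption utility enters both the LEV numerator and (through QoL) the
  denominator of the QALY price; the possible double counting is a known
  open issue of the framework and is not decomposed here.
- Risk-specific VSL (e.g. cancer premiums), covariate-adjusted VSL, QoL
  *improvement* scenarios and the costs of the interventions themselves are
  out of scope.
- The weighted-QALY levels on the synthetic preset (e.g. SCN2's low
  average) are preset-dependent; only orderings and mechanism-level claims
  are asserted in the tests.
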