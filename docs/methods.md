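# Methods

## Model

All quantities derive from Bayes' theorem applied to a dichotomous
screening test with sensitivity *a* ∈ (0, 1] and specificity *b* ∈ (0, 1)
in a population with disease prevalence φ:

- **PPV** ρ(φ) = aφ / (aφ + (1−b)(1−φ)). Strictly increasing in φ whenever
  Youden's J = a + b − 1 > 0; ρ(0) = 0, ρ(1) = 1.
- **Retention ratio** ζ(φ₀, k) = ρ(φ_k)/ρ(φ₀) with φ_k = φ₀ − k, the
  fraction of predictive value kept after prevalence falls by k. Two
  algebraically identical routes are implemented — the quotient of two ρ
  evaluations and the expanded form
  [φ_k(1−b) + Jφ₀φ_k] / [φ₀(1−b) + Jφ₀φ_k] — and their agreement is
  regression-tested to 1e−12. For rising prevalence the fraction's terms
  flip (`zeta_flipped`); the falling-direction type rejects reversed input
  rather than flipping silently, so data errors surface.
- **Prevalence threshold** φ_e = √(1−b) / (√a + √(1−b)), the inflection of
  the ρ-vs-φ curve. The canonical implementation is this radical-conjugate
  form, defined for every constructible test; the equivalent Youden-ratio
  form (√(a(1−b)) + b − 1)/J is kept as a secondary path (it divides by J,
  so it is restricted to J > 0) and the two are property-tested to agree to
  1e−12. The PPV at the threshold collapses to ρ(φ_e) = φ_e·√(LR+) with
  LR+ = a/(1−b).
- **Scenario classification**: with φ₀ > φ_k, either both sit below φ_e
  (threshold above — the steep limb, worst losses), both above (threshold
  below — ζ stays near 1), or the decline crosses φ_e. Boundary equalities
  classify as crossed, treating k = φ₀ − φ_e as the limiting crossing.
- **Serial testing**: n consecutive positives multiply the prior odds by
  LR+ⁿ, so the cumulative PPV is odds/(1+odds) with
  odds = φ/(1−φ)·LR+ⁿ. The smallest n reaching a target ρ is
  ⌈ln[ρ(φ−1)/(φ(ρ−1))]/ln LR+⌉, clamped below at 1 (the count is of tests
  actually performed). Targeting ρ(φ_e) gives the positive test iterations
  (PTI) needed to neutralise the paradox at prevalence φ. **Assumption**
  (not configurable): repeat tests are conditionally independent given
  disease status. Correlated errors — same specimen, same interferent —
  make these counts optimistic.
- **SIR-P**: a Kermack–McKendrick SIR model without vital dynamics in
  population fractions (ds/dt = −βis, di/dt = βis − γi, dr/dt = γi,
  R₀ = β/γ). The infected fraction i(t) is read as the prevalence at t, and
  each weekly record is annotated with ρ, ζ against a reference prevalence
  φ₀, and PTI. The literature sometimes writes the prevalence slot of the
  coupled PPV as the incidence dI/dt; here prevalence is the standing
  infected fraction I(t)/N, which is what a cross-sectional screen samples
  and what reproduces the worked example's published PPV column.

## Parameters

| Parameter | Meaning | Units | Default | Why |
|---|---|---|---|---|
| `sensitivity` | true positive rate a | probability | 0.95 (worked example) | high-grade screening test |
| `specificity` | true negative rate b | probability | 0.99 (worked example) | idem; b = 1 rejected (LR+ undefined) |
| `beta` | infection rate β | /week | 0.93 | see demo calibration below |
| `gamma` | recovery rate γ | /week | 0.16 | idem (R₀ ≈ 5.8) |
| `s0, i0, r0_init` | initial fractions | — | 0.9999, 0.0001, 0 | single seed case per 10⁴ |
| `t_end` | weekly records | weeks | 34 | covers the full wave |
| `dt` | integrator step | weeks | 0.01 | error ≪ display precision |
| `phi0_policy` | ζ reference | — | peak | every later week is then a falling-prevalence comparison; `first`/explicit values available |

The demo β and γ are calibration targets, not data: they are chosen once so
the default simulation is qualitatively like the packaged worked example —
prevalence peaking near 0.52 around week 14 with near-total final attack
rate. The rate constants behind the packaged series itself are not
published, which is exactly why `build_table` exists: it couples ρ/ζ/PTI to
*any* supplied weekly prevalence column, so the published series is
re-analysed as fixture input rather than imitated.

## The packaged worked example, and what passing means

`table1_fixture()` carries the 34 printed weekly infected fractions
(4 decimal places) of a worked example for the 95%/99% test. The suite
regenerates the PPV, ζ and PTI columns from that column alone.

The published PPV/ζ values were computed from *unrounded* prevalences. The
derivative dρ/dφ exceeds 1 below φ_e, so wherever φ < φ_e the 4-dp printed
prevalence cannot pin the 4th decimal of ρ: the published and regenerated
values can legitimately differ by a few units in the last digit (e.g. week
2: ρ(0.0002) = 0.0186 vs 0.0196 printed). The tests therefore assert

1. **strict 4-dp equality** on the rows that are self-consistent at print
   precision (PPV: weeks 1, 9–20, 23; ζ: weeks 1, 10–19), and
2. **interval consistency** on all 34 rows: the printed value must lie in
   the image of ρ (or of the ζ ratio) over the ±5e−5 interval around the
   printed prevalence — interval arithmetic on the declared print
   precision, with no tuned tolerance.

The integer PTI column is robust to input rounding and reproduces exactly
on all 34 rows. Passing these checks shows the closed forms and the
coupling are implemented correctly at the table's precision; it says
nothing about real screening programmes, where test errors correlate
across repeats, prevalence is estimated with sampling noise, and epidemics
are not deterministic SIR flows.

## Numerical choices

- **Integrator**: fixed-step classical 4th-order Runge–Kutta, dt = 0.01
  week, outputs at integer weeks; only (s, i) are integrated and
  r = 1 − s − i recovers the third compartment, making conservation exact
  to rounding. A fixed step keeps runs bit-reproducible; the exact flow
  invariant S(t) = S(0)·e^(−R₀(R(t)−R(0))) is the independent accuracy
  oracle in the tests (agreement within 1e−4; observed ~1e−9 at the default
  step). Non-finite states abort with `IntegrationError`.
- **Ceilings**: the iteration formula snaps values within 1e−9 of an
  integer before applying ⌈·⌉, so a log-ratio that is exactly integral is
  not pushed up a step; agreement with brute-force serial updating is
  tested over 1,000 seeded random draws (exact integer equality).
- **Tolerances**: 1e−12 for single-expression algebraic identities, 1e−10
  for composed expressions; human-facing output rounds to 4 dp (the worked
  example's print precision) while JSON output keeps full precision.
- **Degenerate inputs**: specificity = 1 is rejected at construction (LR+
  undefined); prevalence 0 and 1 are allowed in ρ but not in odds-based
  serial updating; J ≤ 0 blocks threshold-dependent operations, except
  ρ(φ_e) itself which remains defined at the chance-level boundary J = 0
  (it degenerates to φ_e); zero reference prevalence makes ζ undefined and
  raises rather than returning infinity.

## Design choices on open points

- ζ is implemented as the algebraic ratio only; treatments of ζ(φ₀, k) as a
  joint sensitivity object in its two arguments add nothing computable here.
- The iteration formula is a plain ceiling at the supplied target PPV; it
  reproduces every published count.
- Serial testing with a *different* second test is out of scope by design:
  iteration counts across heterogeneous tests are not well defined, and the
  API accepts a single `TestCharacteristics`.
- Negative predictive value, ROC construction, confidence intervals and
  imperfect gold standards are out of scope.

## Known limitations

- The conditional-independence assumption for serial tests is strong; PTI
  values are lower bounds under positively correlated repeat errors.
- The SIR model is deterministic, closed (no births, deaths, imports) and
  homogeneous; it illustrates prevalence sweeps rather than forecasting.
- `build_table` trusts the supplied prevalence series; values are validated
  as fractions but not smoothed or noise-corrected.
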