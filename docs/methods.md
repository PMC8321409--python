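# Methods

## Model and assumptions

The package implements a deliberately minimal mechanistic chain from Aβ
assembly kinetics to population-level AD epidemiology:

1. **Kinetics.** Monomers and dimers follow mass-action ODEs with
   zeroth-order production *S*, first-order clearance *κ*, second-order
   dimerization *ν*, first-order dissociation *μ*, and a trimer sink
   *νMD*. No explicit higher-order oligomer species are tracked: at the
   baseline concentrations the trimer channel removes a negligible mass
   fraction, so the sink term is retained but nothing downstream of it.
2. **Separation of timescales.** Dimer equilibration (~1/μ ≈ 2.5 s) and
   monomer relaxation (~1/κ ≈ 4.5 h) are both fast against the decadal
   drift of the rate constants, so all epidemiological quantities use the
   quasi-static solutions M = S/κ, D = νM²/μ. The full ODE integrator
   (`kinetics.integrate_kinetics`, stiff BDF with analytic Jacobian)
   exists to *validate* this reduction, not to drive the curves.
3. **Toxicity and risk.** Only dimers are toxic: ∂V/∂t = −σDV. AD onset
   is probabilistic with hazard ω(t) = γU(t), where U = σD is the
   neuronal damage rate and γ ∈ (0, 1] the neuronal-death elasticity of
   AD risk. Survivorship is H = V^γ; prevalence counts onsets within the
   last T_D years; no background mortality or competing risk is modeled.
4. **Aging.** The dynamic model drifts S up and κ down linearly:
   S(t) = S̄(1 + t/λ_S), κ(t) = κ̄(1 − t/λ_κ). All rates collapse into
   U(t) = U₀Ξ(t) with Ξ(t) = (1 + t/λ_S)²/(1 − t/λ_κ)², times
   (1 + t/λ_σ) when the age-dependent toxicity variant is enabled. The
   model is only valid for t < λ_κ = 114 y, where clearance reaches zero;
   evaluation beyond that age raises a domain error.

## Parameters and conventions

Internal computation is SI (molar, seconds); user-facing ages and
durations are years (1 y = 3.1536e7 s). Parameters are stored at the
3 significant figures they are reported with; no hidden precision.
Key defaults (general population): S̄ = 3.63e-12 M/s, κ̄ = 6.15e-5 /s,
ν̄ = 115 M⁻¹s⁻¹, μ̄ = 0.400 s⁻¹, σ̄ = 4.94 M⁻¹s⁻¹, γ = 0.601,
λ_S = 154 y, λ_κ = 114 y; Down's syndrome uses S̄ = 5.45e-12 M/s and
λ_S = 86.2 y with everything else shared. Two conventions deserve note:

- **Units of ν̄ and μ̄.** The source table's unit labels for these two
  rates are swapped relative to what dimensional analysis of the ODEs
  requires; the package uses the dimensionally consistent assignment
  (ν̄ in M⁻¹s⁻¹, μ̄ in s⁻¹), which also reproduces the ~40%-per-second
  dimer turnover.
- **Two survival times T_D.** The parameter table carries both 7.1 yr
  and 2.23e9 s (≈70.7 yr) for survival after diagnosis; these are not
  the same duration, and different published summary numbers were
  computed with different choices. Both are stored on `ParameterSet`;
  callers select explicitly via `T_D_in_years(p, "years"|"seconds")`.
  The static prevalence plateau (0.0663%) needs the year value; the
  Down's-syndrome prevalence ratios (2.24, 3.15) need the seconds value.
- **The AD-pathology factor F** is carried as 3.63 where volume ratios
  are reproduced and 3.65 where the spread relation Σ*/U* = √(F−1) is
  used — the source itself uses both roundings.
- **Derived scales.** `derived_scales` computes M̄ = S̄/κ̄,
  D̄ = ν̄M̄²/μ̄, Ū = σ̄D̄, ω̄ = γŪ, x̄ = √(D_M/κ̄), t̄ = 1/κ̄ from the
  stored constants. Because the published derived values were rounded
  from unrounded internals, recomputation agrees to ~0.4% rather than
  exactly; `parameters.PRINTED_SCALES` keeps the published roundings for
  code that needs to reproduce downstream numbers to their printed
  precision (e.g. ω̄ = 9.34e-5 /yr).

## Numerical choices

- **Closed-form Ξ integral.** Ξ is a rational function of age; the
  substitution u = 1 − t/λ_κ turns ∫Ξ dt into ∫(polynomial in u)/u² du,
  integrated term by term and normalized so Φ(0) = 0. The same route
  handles the cubic numerator of the age-dependent-toxicity variant.
  All prevalence/risk integrals use this antiderivative; adaptive
  quadrature appears only as a cross-check (tests assert agreement to
  1e-9 relative over 2000 random windows per schedule).
- **ODE integration** uses `solve_ivp(method="BDF")` with analytic
  Jacobian, rtol 1e-10 and concentration-scaled atol; output grids are
  log-spaced by default because the system spans seconds to decades.
  Quasi-static tracking holds to <1e-3 relative in M through age ~85 y;
  nearer λ_κ the monomer pool genuinely lags the shrinking clearance
  (1.6e-3 at 90 y, 8e-3 at 100 y, confirmed with two independent stiff
  integrators), consistent with the model's descriptive validity ending
  around age 90.
- **Spatial solution.** The focal-source profile is the piecewise
  sinh/cosh kernel solution with decay constant √(κ̄/D_M); dimers are
  slaved to M² (no dimer PDE — dimers barely diffuse before
  dissociating). The independent oracle solves the steady radial problem
  via w = rM and second-order central differences on a uniform grid with
  the source-discontinuity radius X* placed exactly on a node (the
  interface node takes the mean source); far field is Dirichlet at
  R_max = 20x̄. Agreement is ≤1e-3 relative on (0, 10x̄] at the default
  4000-point grid, with observed ~4× error reduction per grid halving.
- **Doubling times** come from OLS of log₂(curve) against age on a
  1-year grid over 60–90 y (the window that matches both published
  doubling times; the source does not state its window), returning
  1/slope and +inf for nonpositive slopes.
- **Elasticities** are computed analytically where the response is a
  power law and by Richardson-refined central differences (relative step
  1e-6) otherwise; the two routes are asserted to agree to 1e-6.
- **Fits.** σ and the TBI slope use weighted nonlinear least squares
  (`scipy.optimize.curve_fit`, inverse-variance weights, linearized 95%
  intervals). The σ fit normalizes to the zero-concentration control and
  treats the assay's oligomer concentration as the dimer concentration
  in V = exp(−σDt); an `errors="sd"` option mirrors the alternative
  reading of assay error bars (identical point estimate, rescaled CI).
  The TBI fit excludes the definitional n = 0 anchor by default; an
  `include_anchor` option covers the other convention.
- **Cohort simulator.** Each individual draws U₀ from a finite discrete
  distribution and an Exp(1) variate; the onset age solves
  γU₀Φ(t) = E exactly (closed-form Φ, monotone-interpolant bracket plus
  Newton polish — onsets are continuous, never discretized to years).
  One root `SeedSequence` spawns per-replicate streams whose ids are
  recorded. The prevalence estimator divides prevalent cases by the
  at-risk count at the window start t − T_D, because the analytic
  P(t) = 1 − exp(−∫_{t−T_D}^t I) is the onset probability conditional on
  being AD-free when the window opens; the crude cases/N₀ variant is
  also exposed (it sits below the closed form by the survivor factor,
  ~5% at age 90).

## Synthetic data

The generators in `fixtures` emulate the *structure* of the external
tables the fitting routines consume — viability assays (24 h exposure,
concentration-indexed rows, multiplicative Gaussian noise with the se
column carrying the true per-row sd) and TBI hazard-ratio tables
(additive Gaussian noise) — using the model's own assumed forms as
truth. Passing recovery tests therefore demonstrates that the estimators
are correct and unbiased under the model's error structure; they say
nothing about model misspecification, digitization error, or the
covariate adjustments present in the real clinical sources, none of
which are emulated.

## Problem sizes

The routine suite runs the quadrature cross-check at 2000 random
windows, Monte-Carlo recovery at 300–500 replicate fits, the Jensen
property at 100 randomized distributions, and cohorts up to 40,000
individuals × 200 replicates (static) and 40,000 × 50 (dynamic); the
finite-difference oracle uses 4000-point grids. The full suite completes
in well under a minute on one CPU.

## Known limitations

- No background mortality, competing risks, sex stratification or
  birth-cohort structure; prevalence saturates at 1 by construction.
- The quasi-static reduction (and hence every closed-form curve)
  degrades within the last ~20 years before λ_κ; nothing here should be
  interpreted past age ~90.
- The spatial model is steady-state with static rate constants, an
  idealized spherical geometry, and no boundary (no blood–brain
  barrier); its published prose "≈20%/≈40%" center elevations are not
  reproduced by the printed closed form, which gives ≈13.7% for the
  monomer at the default configuration — the package follows the
  formula.
- γ, the TBI slope a = 0.231, and F are taken as published constants;
  the external clinical datasets behind them are not refit.
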