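# abdimer

A monomer–dimer kinetic model of Alzheimer's disease (AD) etiology, as a
tested Python library and command-line tool. The package is aimed at
computational neuroscientists and epidemiological modellers who want a
mechanistic, fully explicit bridge from amyloid-β (Aβ) reaction kinetics
to lifetime disease risk: every population-level curve is derived from a
handful of cell-scale rate constants.

## The model

Aβ monomers (concentration *M*) are produced at rate *S* and cleared at
rate *κ*; two monomers dimerize at rate *ν* and dimers (*D*) dissociate
at rate *μ*, with a trimer sink *νMD*:

    dM/dt = S − κM − 2νM² − νMD + 2μD
    dD/dt = νM² − μD − νMD

Dimer turnover is fast (~1/μ ≈ 2.5 s) and monomer relaxation
intermediate (~1/κ ≈ 4.5 h), while the rate constants drift over
decades, so away from transients the system is quasi-static:
*M* = *S*/*κ*, *D* = *νM*²/*μ*. Dimers are toxic: neuronal viability
decays as ∂V/∂t = −σDV, and the per-percent link between neuronal loss
and AD risk is the elasticity γ, giving

    U(t) = σνS²(t)/(κ²(t)μ) = U₀Ξ(t),   ω(t) = γU(t),
    V(t) = exp(−∫₀ᵗU),  H(t) = V^γ,  I(t) = ω(t),
    P(t) = 1 − exp(−∫_{t−T_D}^t I),  Υ(t₁,t₂) = 1 − exp(−∫_{t₁}^{t₂} I).

Aging enters through linear schedules *S*(*t*) = S̄(1 + *t*/λ_S) and
*κ*(*t*) = κ̄(1 − *t*/λ_κ) (optionally σ(*t*) = σ₀(1 + *t*/λ_σ)), which
make the dimensionless factor Ξ(*t*) = (1 + *t*/λ_S)²/(1 − *t*/λ_κ)²
grow steeply with age. Its antiderivative is available in closed form,
so viability, incidence, prevalence and lifetime risk are evaluated
without numerical quadrature. The package also provides:

- a spherically symmetric steady solution for a focal sphere of excess
  monomer production (with an independent finite-difference oracle),
- the TBI relative-hazard model R̂(n) = (1 + an)² and its weighted fit,
- elasticity (sensitivity) analysis and damage-rate heterogeneity
  (conditional means given disease status, Jensen effects on prevalence),
- a stochastic individual-level cohort simulator with replicate bands,
- calibration routines (σ from viability assays, γ from an incidence
  anchor, the AD-pathology factor F from hippocampal-volume loss rates).

## Worked example

```python
import abdimer as ab

p = ab.default_parameters("general")     # baseline rate constants
ds = ab.derived_scales(p)
print(f"M_bar = {ds.M_bar:.3g} M, D_bar = {ds.D_bar:.3g} M")
print(f"U_bar = {ds.U_bar:.3g} /s ({ds.U_bar_per_year:.3g} /yr)")

h = ab.dynamic_hazard(p)                 # linear S and kappa drifts
print(f"incidence at 60: {float(h.incidence(60.0)):.3g} /yr")
print(f"HV loss rate at 75: {100*h.hv_annual_change(75.0):.2f} %/yr")
print(f"lifetime risk 60->78.5: {100*h.lifetime_risk(60.0, p.T_L):.2f} %")
print(f"incidence doubling time: {ab.incidence_doubling_time(h):.1f} y")

hd = ab.dynamic_hazard(ab.default_parameters("down"))
ratio = ab.scenario_ratio(hd, h, "prevalence", 80.0,
                          T_D=ab.T_D_in_years(p, "seconds"))
print(f"Down/general prevalence ratio at 80: {ratio:.2f}")
```

prints

```
M_bar = 5.9e-08 M, D_bar = 1e-12 M
U_bar = 4.95e-12 /s (0.000156 /yr)
incidence at 60: 0.000807 /yr
HV loss rate at 75: 0.29 %/yr
lifetime risk 60->78.5: 2.47 %
incidence doubling time: 11.2 y
Down/general prevalence ratio at 80: 3.18
```

Reading this: at baseline the brain holds ~59 nM of monomer and ~1 pM of
dimer, killing neurons at ~0.016%/yr at birth. The age-driven drift in
production and clearance raises the neuronal damage rate ~19-fold by age
75 (0.29%/yr of hippocampal volume), makes AD incidence double every
~11 years, and gives a 60-year-old a ~2.5% risk of developing AD by
78.5. The 50% higher Aβ production in Down's syndrome more than triples
prevalence at 80 because risk scales with the *square* of production.

The same computations are exposed as a CLI:

```sh
abdimer epi --scenario down --ratio-vs general --age 80 --td seconds
abdimer spatial-profile --rho 0.231 --xstar-factor 2 --ages 40,60,80
abdimer population-sim --n0 40000 --years 90 --replicates 200 --seed 7
```

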