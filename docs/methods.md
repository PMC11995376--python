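# Methods

## Scope and state variables

`anomer` models a solvent (water) plus two isomers in chemical equilibrium
(the lactose anomers), optional inert foreign sugars, and one crystalline
phase (α-lactose monohydrate). All thermodynamics is evaluated on the
mole-fraction basis; mass fractions of solution and grams per gram of water
are derived views, converted at a fixed context composition so the basis
maps are linear and exactly commutative. The two anomers share a molar
mass (342.30 g/mol), which makes their mole and mass ratios identical — an
identity the mutarotation rate law and several consistency checks rely on.

## Activity model

The solvent activity coefficient is the 2-suffix Margules form
ln γ_w = A(1 − x_w)², with A dimensionless, temperature specific and
composition independent. Integrating the Gibbs–Duhem relation from
infinite dilution, with the isomer pair treated as a single pseudospecies,
yields ln γ*_iso = A(x_w² − 1) in the solute standard state. Resolving the
group requires the equilibrium ratio K_x(x_w) = x_β/x_α; chemical
equilibrium forces d ln a_β = d ln a_α, and integrating each isomer's
Gibbs–Duhem balance from infinite dilution (where a_β = K* a_α) gives the
closed forms

    ln γ*_α = A(x_w² − 1) + ln[(1 + K_x)/(1 + K*)]
    ln γ*_β = A(x_w² − 1) + ln[(1 + 1/K_x)/(1 + 1/K*)]

valid for *any* functional K_x(x_w). Three checks pin the forms down and
run in the test suite: (i) ln γ*_α − ln γ*_β = ln(K_x/K*) holds to 1e-12
over randomized parameters; (ii) a trapezoidal Gibbs–Duhem integrator that
assembles the per-isomer integrand directly from the balance (not from the
closed forms) reproduces them to better than 1e-6 relative at 1e4 steps;
(iii) the group coefficient equals the corrected geometric average of the
per-isomer ones. The numerical integrator handles the individually
singular terms at x_w → 1 by substituting their exact finite limit within
1e-12 of pure water, and verifies its own convergence by step doubling.

K_x(x_w) is linear, K_x = K* − slope·(1 − x_w), matching how K* is
estimated in practice (linear extrapolation of measured ratios to
x_w → 1). The default slope is 0: no slope value is tabulated for
lactose, and every equilibrium quantity the package reports (K_sp, the
saturation point) is algebraically slope invariant, which the tests assert
at slopes {0, 1, 3}. A positive slope of order 1–3 reproduces the observed
mild decrease of K_x with solute content and can be set in the config.

**Validity window.** Composition-dependent evaluations are restricted to
x_w ∈ [0.9, 1]; outside it the model raises rather than extrapolating,
because the Margules fit is calibrated on dilute-to-supersaturated
solutions only.

## Default parameters (25 °C lactose–water)

| symbol | meaning | default | unit |
|---|---|---|---|
| A | Margules constant | −5.8 | — |
| K* | thermodynamic mutarotation constant (β:α at infinite dilution) | 1.60 | — |
| slope | dK_x/dx_w | 0.0 | — |
| k_α | forward mutarotation rate constant | 0.64 | 1/h |
| K_sp | solubility product of the monohydrate | 0.00494 | — |
| ρ_c | crystal density | 1545 | kg/m³ |
| k_v | volumetric shape factor (spheres) | π/6 | — |
| χ | anhydrous mass fraction of the hydrate (computed, = M_α/M_hydrate) | 0.95 | — |
| k_D | dissolution rate constant | 1e-3 | m/s |
| seed PSD | Gaussian mean / sd | 10 / 1 | μm |

K* is not independently tabulated; 1.60 is the unique value consistent
with K_sp = 0.00494 at the saturation water fraction 0.9886 for A = −5.8,
and matches the literature β:α ratio of lactose. χ is always computed from
the registry molar masses, never hard coded.

## Solid–liquid equilibrium

At saturation K_sp = a_w γ*_α x_α with unit solid activity. The
equilibrium point (simultaneous saturation and mutarotation equilibrium)
is found by bracketed Brent root finding of
x_α,sat(x_w)(1 + K_x(x_w)) = 1 − x_w on x_w ∈ (0.9, 1 − 1e-9), with the
residual required below 1e-12. Foreign-sugar solubility uses the same
K_sp, A and K_x(x_w) with the water fraction reduced by the foreign moles
— the modelling hypothesis is that activity coefficients depend on the
total sugar content (through x_w), not on which sugars make it up. The
prediction is therefore exact to the extent a foreign sugar shares the
lactose Margules constant; disaccharides do approximately, monosaccharides
less so, and the package deliberately does not carry sugar-specific
Margules constants into this prediction.

The depression parameter F = −dx_α,sat/dx_β comes from a first-order
Taylor expansion of x_α,sat(x_w) about the equilibrium point combined with
the mole-balance closure Δx_w = −Δx_β − Δx_α,sat, giving F = S/(1 + S)
with S = dx_α,sat/dx_w evaluated at the equilibrium point. The default evaluation holds K_x constant at
its saturation value, since its composition dependence enters S only
through a small correction term; a slope-inclusive mode exists for
sensitivity analysis. `convert_F_basis` rescales F between bases with
frozen-context Jacobians (the ratio of the species' basis-conversion
slopes at the reference composition), so for two equal-mass species F is
basis invariant, and a light depressant like glucose rescales by the
molar-mass ratio.

## Regime classification

The initial suspension density (g powder per g water) is compared directly
with c_α,sat,eq and c_tot,sat,eq on the same basis: below the first the
powder dissolves in seconds (Type I), above the second solids persist
through mutarotation equilibrium (Type III), between them the solid
vanishes only after mutarotation undersaturates the solution (Type II).
Near the II/III boundary the diagram is approximate: the water released by
the hydrate (1 − χ = 0.05 g per g dissolved) shifts the exact
full-dissolution boundary from c_tot,sat,eq = 0.2191 up to
c_tot,sat,eq/(χ − (1 − χ)c_tot,sat,eq) ≈ 0.2333 g/g, so loadings in that
narrow band classify as Type III by concentration comparison yet fully
dissolve (marginally) in the simulator. Simulation studies of the
persistent-suspension regime in the tests therefore use 0.25 g/g, safely
above the band.

## Dissolution simulator

State: dissolved masses (m_α, m_β, m_w) plus the crystal population. The
rate laws are first-order reversible mutarotation referenced to solution
mass, r = k_α c_α − (k_α/K_x) c_β (zero exactly at the equilibrium
ratio), and a size-independent linear driving force D = k_D(x_α,sat − x_α)
with x_α,sat = K_sp/(a_w γ*_α) evaluated at the instantaneous x_w — i.e.
the mutarotation-equilibrium activity expressions are reused off
equilibrium, on the hypothesis above. The driving force is clamped at
zero from below (the model describes dissolution only; no growth).

The population balance is solved by the method of characteristics: the
Gaussian seed is discretised into 200 equal-probability characteristics at
quantile midpoints (third moment accurate to ~2e-4 at the default PSD),
with number weights per kg suspension that are constant in time. Because
D is size independent, all characteristics shrink in lockstep, so the
population is evolved exactly through one cumulative decrement ℓ(t) with
L_i(t) = max(L_i(0) − ℓ, 0) — no numerical diffusion, and vanished
characteristics drop out of the moments without restarting the
integrator. Per-characteristic zero crossings are registered as
non-terminal integration events to keep the error controller honest at
the kinks; the complete-dissolution event (ℓ reaching the largest seed)
terminates phase 1, and the solids-free relaxation continues as phase 2.

Integration is adaptive LSODA at rtol 1e-10 / atol 1e-15 in SI units
(kg, m, s; user-facing hours and μm), resolving the seconds-scale
dissolution transient rather than skipping it. Conservation of lactose
(m_α + m_β + χ m_cry), water (m_w + (1 − χ) m_cry) and total suspension
mass is not imposed algebraically — the three balances are integrated —
and holds to ≤ 1e-8 relative in the tests, which is therefore a genuine
check on the integration. A separate 0-D quasi-equilibrium reference
(α pinned algebraically to saturation while solids last, only β
integrated, solids from conservation) reproduces the full simulator's
c_β(t) within 1% beyond the transient and provides the skip-transient
approximation explicitly.

Two time-scale facts worth knowing when choosing horizons: a clear
solution relaxes to mutarotation equilibrium at k_α(1 + 1/K_x) ≈ 1.04 1/h,
effectively complete by 12 h; a persistent suspension relaxes more slowly,
at roughly k_α/K_x + k_α F ≈ 0.43 1/h, because dissolution keeps
replenishing α — end-state checks on suspension runs therefore use a 24 h
horizon.

## Synthetic data generator

`fixtures` emulates the measurement tables the calibration assumes:
a_w = x_w exp(A(1−x_w)²) plus additive Gaussian noise (sd 5e-4, the
precision of a good dew-point water-activity meter) on 20 compositions in
x_w ∈ [0.96, 0.999], and K_x = K* − slope(1−x_w) plus noise (sd 0.01) on
15 compositions, both seeded and bit-reproducible. What it does *not*
emulate: heteroscedastic or correlated replicate error, composition
measurement error in x_w itself, sparse/uneven experimental designs, and
any systematic model misfit (the truth is exactly Margules / exactly
linear). Passing recovery tests therefore demonstrate the estimators are
correct and calibrated under the assumed error model, not that real
measurements obey it.

One statistical consequence, documented rather than hidden: at these
table sizes an interval of ±2 estimated standard errors has exact coverage
P(|T_df| ≤ 2) ≈ 0.94 (df = 19) and 0.93 (df = 13), not the asymptotic
0.9545, so a coverage study over 200 seeds lands near 92–94%.

## Degenerate inputs and numerical choices

Compositions are validated to [0, 1] and renormalised from within 1e-9 of
unit sum; all-saturated (x_w = 1) calibration designs raise; K_x ≤ 0
anywhere in the validity window raises at model construction; foreign
loadings large enough to push saturation below x_w = 0.9 raise a validity
error; a zero-sd seed PSD degenerates to a single characteristic; zero
loading runs produce exact all-zero lactose series. Root solves use Brent
with xtol 1e-15 on brackets fixed to the validity window. Ties at regime
boundaries resolve to Type II (the classifier uses strict inequalities
against both thresholds).

## Known limitations

* Two isomers only; three-isomer systems (e.g. fructose) have no closed
  forms here and would need the numerical integration path generalised.
* All parameters are 25 °C values; other temperatures enter only through
  user-supplied parameter sets, with no built-in temperature dependence.
* No nucleation, growth, agglomeration or breakage; the simulator
  describes dissolution of an existing seed population only.
* Foreign-sugar predictions share the lactose Margules constant by
  design; quantitative accuracy degrades for sugars with very different
  hydration behaviour (monosaccharides).
* The mutarotation-equilibrium activity expressions are reused away from
  equilibrium; this is a modelling hypothesis validated by the internal
  consistency of the dissolution model, not a thermodynamic identity.
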