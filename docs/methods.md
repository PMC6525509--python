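# Methods

This note records the models, parameter choices and numerical decisions
behind `pondn2o`, and what the synthetic-data tests do and do not
demonstrate about real survey data.

## Physical chemistry

Solubility uses the seawater-scale fits: the N₂O Henry coefficient K₀
(mol L⁻¹ atm⁻¹) from Weiss & Price (1980) and the CH₄ Bunsen coefficient
from Yamamoto et al. (1976) divided by 22.414 L mol⁻¹. Both share the form
ln X = A₁ + A₂(100/T) + A₃ ln(T/100) + S(B₁ + B₂(T/100) + B₃(T/100)²) and
are shipped as a coefficient table (`data/gas_coefficients.csv`) rather
than hard-coded, so alternative parameterizations can be swapped. Validity
spans the survey range (−2…40 °C, S ≥ 0); the functions are continuous and
monotone decreasing in temperature and salinity, which the tests verify on
a 0.5 °C grid against independently typed coefficient tables.

Dry GC molar fractions are converted to partial pressures against
*moist* air, p = x·(P − p_H₂O(T, S)), using the Weiss & Price vapor
pressure fit; the correction (~2–3% at 20 °C) is on by default and
toggleable. At the 2017 global mean mixing ratio of 0.33 µatm, the
resulting equilibrium concentration crosses ~8.83 nM near 21.5 °C —
mid-summer surface temperature — which anchors the classification
baseline.

Schmidt numbers use the Wanninkhof (1992) freshwater third-order
polynomials (0–35 °C), with a linear freshwater↔seawater interpolation for
brackish sondes. Transfer velocities convert between gases by
k_target = k_source (Sc_target/Sc_source)^(−n) with n = 0.67, the standard
negative-exponent convention for a turbulent surface; since
Sc_N₂O ≈ Sc_CH₄ at survey temperatures the conversion factor is within
~1% of unity. `convert_k` is exactly self-inverse, and an exponent of 0 is
the identity (property-tested).

## Headspace mole balance

For a bottle of water volume V_w with an added air headspace V_g at total
pressure P and temperature T, conservation of analyte moles gives

C₀ V_w + x_air·n(V_g) = K₀ p_f V_w + x_hs·n(V_g),  n(V_g) = (P − p_H₂O) V_g / RT,

where p_f is the partial pressure implied by the measured post-shake
headspace fraction x_hs. Solving for C₀ is linear and exact; the forward
simulation is its algebraic inverse, and the suite checks the round trip
to 1 part in 10⁹ over randomized bottles (plus a brute-force Brent-solve
oracle of the same balance written independently). The fixed point is by
construction: water in equilibrium with the added air returns exactly the
equilibrium concentration.

Replicates are back-calculated individually and averaged; their sample
standard deviation is the per-site analytical uncertainty, and the fleet
mean of those σ values is the classification half-band (≈1.25 nM under
default generator noise). A back-calculated concentration below numerical
tolerance is *flagged* (`negative_concentration`), never clamped.
Equilibration is evaluated at the field surface-water temperature; a lab
temperature column can be configured instead where bottles were
equilibrated indoors.

## Chamber transfer velocities

Chamber N₂O accumulation over 10 minutes is usually within analyzer
accuracy, so k comes from the co-measured CH₄ series. Three ordered QC
rules reject a series: total change ≤ 2% of the series mean
(`below_accuracy`), regression r² < 0.7 (`low_r2`), and any single
between-sample increment exceeding 3× the median absolute increment
(`ebullition_step`). The first and second thresholds follow the field
protocol; the step rule is our own quantitative reading of "step-like
jumps", chosen to be scale-free and robust for 5-point series, with the
multiplier configurable. A zero-variance series has r² defined as 0 so the
degenerate 0/0 case rejects cleanly.

Flux is f = s·V/(V_m·S)·1440 (µatm min⁻¹ × L / (L mol⁻¹ × m²) → µmol m⁻²
d⁻¹), with the ideal-gas molar volume at local pressure and air
temperature (defaulting to surface-water temperature when no air
temperature was logged). Fick inversion gives k = f/(K₀ Δp)·10⁻³ m d⁻¹; a
k opposing the gradient is flagged rather than silently negated. The fleet
k_N₂O is the mean ± SD over accepted incubations, and sites without their
own chamber inherit the fleet mean — the same extrapolation a survey
makes.

## Stratification

Density comes from the standard freshwater polynomial (maximum at
~4 °C; optional linear haline term, off by default since profiles carry
temperature only). N² is computed at layer midpoints as (g/ρ̄)Δρ/Δz with
depth positive downward (warm-over-cold ⇒ N² > 0); a centered-difference
variant is available since the exact scheme of profile-analysis routines
varies. Raw interface values keep their sign; the per-site statistic
max(0, max N²) is reported in s⁻² (i.e. N², following common limnological
reporting).

## The driver GAM

The response is dissolved N₂O (nM, strictly positive), modelled as Gamma
with log link. Terms: univariate smooths of surface/deep DO saturation,
sediment C:N, log Chl-a, surface pH, log TDN:SRP; a tensor-product smooth
of √BF and log DIN; optionally a reservoir random intercept. Chl-a, N:P
and DIN are natural-log transformed and BF square-root transformed before
basis construction (the tensor margins use the transformed axes). A
Pearson screen (|r| ≥ 0.8 by default) reports collinear covariate pairs
first, retaining the higher-priority member of each flagged pair.

Bases: univariate smooths are low-rank 1-D thin plate regression splines
(eigen-truncated |r|³ kernel, null space {1, x}); tensor margins are
4-knot cardinal natural cubic regression splines with the exact
D′B⁻¹D curvature penalty; the random intercept is an indicator block with
a ridge penalty. "Nine basis functions" is interpreted as the
post-identifiability-constraint dimension (k = 10 internally); the
sum-to-zero constraint is absorbed by reparametrizing each block with the
null space of its column-sum constraint, and columns are rescaled to unit
norm for conditioning. With the double penalty on, each smooth also
receives a ridge on the null space of its curvature penalty (computed by
eigendecomposition), so whole terms can shrink to ≈0 EDF.

Fitting: for a Gamma log-link model the Fisher weights are identically 1,
so the penalized IRLS inner loop is a sequence of penalized least-squares
solves of the working response z = η + (y−μ)/μ against a fixed X, with one
Cholesky factorization of (XᵀX + S_λ) per smoothing proposal, step-halving
on the penalized deviance, and convergence on both the penalized deviance
(rel. 10⁻¹⁰; 10⁻¹³ for the final solve) and the coefficient change. The
outer criterion is the Laplace-approximate restricted marginal likelihood

l_r = l(β̂) − β̂ᵀS_λβ̂/2φ + ½log|S_λ/2πφ|₊ − ½log|(XᵀX+S_λ)/2πφ|,

maximized by L-BFGS-B over log smoothing parameters (one per penalty,
bounds e⁻¹⁴…e²²) and the log Gamma scale, finite-difference gradients,
outer tolerance 10⁻⁶, ≤200 iterations. The pseudo-determinant rank is
fixed structurally from the penalty union so widely separated λ's cannot
change the counted rank. EDFs are per-term traces of (XᵀX+S_λ)⁻¹XᵀX;
credible intervals use the Gaussian posterior φ(XᵀX+S_λ)⁻¹ (no
bootstrap); term p-values are Wald-type on the fitted effect values with
rank ⌈EDF⌉, labelled approximate.

Validation: with penalties off the fit reproduces a statsmodels Gamma GLM
on the same basis to < 10⁻⁸ in coefficients; with shrinkage on, per-term
EDFs and fitted values agree closely with `mgcv` (`select=TRUE`,
REML) on identical data (deviance explained within 0.03, fitted
correlation > 0.99 in the cross-check test).

A caution the survey design forces: with exactly one observation per
reservoir, the random intercept is confounded with the Gamma scale — both
our REML and mgcv then drive the RE to absorb all residual deviance
(deviance explained → 1, mgcv issues a non-convergence warning). The
pipeline therefore includes the random intercept only when some reservoir
contributes more than one row; the generator supports replicates so the RE
path is still exercised.

## Literature models

"N₂O-N" denotes the nitrogen mass in N₂O: 28.0134 g N per mol, so
nM = µg N L⁻¹ / 28.0134 × 10³ and N₂O mass = N₂O-N mass × 44.0128/28.0134.
The EF(B) route multiplies NOₓ-N by the 0.0025 surface-water emission
factor, converts to nM, and runs through the bulk flux relation with the
fleet k; with zero NOₓ it predicts zero dissolved N₂O, hence an influx of
k·C_eq — a boundary we document rather than special-case. Coefficients for
the two published linear flux models are *required configuration* with a
citation field; shipping guessed values would misattribute them. Fold
overestimates are |predicted|/|observed| per site over sites where both
are nonzero, summarized by min/mean/max. CO₂ equivalents take the GWP as
configuration (examples use 273).

## The synthetic survey

The generator emulates the statistical structure of a late-summer prairie
survey: 101 sites; TDN, DIN, Chl-a log-uniform over 417–14,280,
32–7,688 and 2.2–2,484 µg L⁻¹ respectively (two–three orders of
magnitude); DO saturation around slightly supersaturated surfaces;
pH 7–10 hard-water ponds; ~28% unstratified columns and BF up to
0.04 s⁻² otherwise; water temperature ~19.5 ± 2.2 °C. True log-scale
effects: surface DO declining above saturation, Chl-a declining, and a
DIN ramp gated by stratification (high DIN raises N₂O only at low BF);
deep DO, sediment C:N, pH and N:P are planted nulls. The response is
Gamma (shape 14) around exp(α + Σf + γ), clipped to 1.14–110 nM.
Headspace bottles are forward-equilibrated from the true concentrations
with 15% multiplicative GC noise on two replicates; chamber campaigns
draw k from a lognormal with mean 1.64 and SD 1.24 m d⁻¹ and plant
2 flat + 2 nonlinear + 3 ebullition violations among 30 incubations;
profiles are two-layer columns solved to hit each site's BF.

The constants α = ln 9.8, effect amplitudes (−0.6 DO, −0.5 Chl-a, +2.65
interaction), shape and GC noise were fixed once, by matching the
generator's own fleet statistics to the survey conditions above (median
≈6.5 nM, replicate σ ≈1.2 nM, a roughly 2:1 sink:source split with ~13%
near equilibrium, ~83% deviance explained); they are configuration, not
fitted quantities. All randomness derives from one seed fanned out to
per-site substreams, so identical seeds reproduce byte-identical datasets
and enlarging the fleet never perturbs existing sites.

What passing tests show — and don't. The generator draws covariates
independently (no spatial autocorrelation across the survey region, no
seasonality), uses exactly the smooth-effect family the GAM can represent,
and its noise is exactly Gamma. Recovery of planted effects therefore
demonstrates the correctness of the estimation machinery, not that real
reservoir N₂O follows these response shapes; QC detection rates apply to
the planted violation forms, and real ebullition may be subtler.

## Problem sizes and runtimes

The shipped checks run at desk scale on one CPU: 1,000-bottle headspace
round trips, 100 chamber recoveries, GAM simulation recovery at n = 300
across ten seeds, and the full 101-site pipeline — a few seconds each, a
couple of minutes end to end. Larger fleets are a matter of configuration
(`n_sites`); the GAM solver is dense and comfortable to a few thousand
rows.

## Known limitations

- CO₂ and O₂ systems, depth-dependent hydrostatic corrections, and
  wind-based k models are out of scope.
- The ebullition detector is one defensible rule, not a field standard.
- Approximate p-values are liberal for heavily shrunk terms; treat them as
  screening, not inference.
- Flux classification treats ties (departure exactly σ) as equilibrium —
  a conservative, closed-band choice.
- The literature comparison reproduces published fold-overestimates only
  when run with the corresponding deposited survey data and the cited
  models' coefficients.
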