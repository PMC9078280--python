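# Methods

## Solid–liquid equilibrium

For a pure crystalline solute in equilibrium with its saturated solution,
equating solid and liquid chemical potentials and neglecting the
solid/liquid heat-capacity difference gives

    x_sat · γ(x_sat, T) = exp[ −(ΔH_fus/R) (1/T − 1/T_fus) ]

with `R = 8.314 J/(mol K)`.  The right-hand side is the *ideal solubility*;
the activity coefficient γ carries all solution non-ideality.  The Δc_p
term is deliberately omitted — the model is used far below the melting
temperature where that term is unconstrained by the available data, and the
fitted/measured enthalpies absorb part of it.  Two consequences follow:

* γ at a *measured* saturation point can be computed from melting
  properties alone (`gamma_from_melting`);
* conversely, a single measured solubility point pins ΔH_fus when the
  calorimetric value is too uncertain (`fit_hfus`).

The saturation solver iterates `x ← x_ideal/γ(x)` starting from the ideal
solubility, with full substitution steps and automatic step halving if the
iteration ever diverges (for these systems γ varies slowly with x, so full
steps converge in ~10 iterations where a fixed 0.5 damping needs ~40); a
bracketed Brent polish guards the rare case where the fixed point stalls
above 1e−8 relative residual.  `fit_hfus` exploits the fact that γ at the
target composition does not depend on ΔH_fus: the saturation condition is
inverted in closed form and a secant iteration on the full forward
prediction removes any residual solver inconsistency (relative residual
≤ 1e−6, typically ≤ 1e−10).

## PC-SAFT equation of state

The reduced residual Helmholtz energy is the perturbed-chain SAFT sum

    a_res = a_hc + a_disp + a_assoc

* `a_hc`: Boublík–Mansoori hard-sphere mixture moments plus the chain
  correction `−Σ xᵢ(mᵢ−1) ln gᵢᵢ(dᵢ)`, with temperature-dependent segment
  diameters `dᵢ = σᵢ(1 − 0.12 e^{−3uᵢ/kT})`.
* `a_disp`: the two universal seventh-order power series in packing
  fraction with the published model constants, the `C₁` compressibility
  correction, and the van der Waals one-fluid sums `m²εσ³`, `m²ε²σ³`.
* `a_assoc`: Wertheim first-order site balance.  Every associating
  component here carries the 2B scheme (one donor site A, one acceptor
  site B; only A–B bonds).  Association strength
  `Δ^{AᵢBⱼ} = σᵢⱼ³ gᵢⱼ(d) κ^{AᵢBⱼ} (e^{ε^{AᵢBⱼ}/kT} − 1)`.

Combining rules: `σᵢⱼ = (σᵢ+σⱼ)/2`, `uᵢⱼ = √(uᵢuⱼ)(1−kᵢⱼ)` with an
optional linear temperature dependence of kᵢⱼ; cross association uses the
arithmetic-mean energy and the σ-ratio-scaled geometric-mean volume
(Wolbach–Sandler).  Water's segment diameter is itself a three-term
exponential in T (stored as data, not hard-coded, so any component may use
the template); it enters every moment, Δ, and derivative consistently.

**Site-balance solver.** Damped successive substitution (factor 0.5) to a
loose 1e−6 tolerance, then Newton on the stacked donor/acceptor system to
machine precision (final residual ≤ 1e−12 enforced, typically ≤ 1e−15).
The tight finish matters: μ-differences between separately solved states
(e.g. dilute mixture vs pure water) must be accurate to ~1e−12 for osmotic
coefficients at 1e−6 mol/kg to approach their unit limit cleanly.

**Derivatives.** Z = 1 + ρ ∂a_res/∂ρ and μᵢ_res/RT = ∂(n·a_res)/∂nᵢ at
constant T, V are computed by *complex-step differentiation*: the Helmholtz
routine accepts complex density and mole numbers (the association solve is
continued analytically), so `Im f(z+ih)/h` with h = 1e−150 is exact to
machine precision with no subtractive cancellation.  The implicit
dependence of the site fractions is differentiated exactly because the
Newton polish converges the perturbed balances too.  Real central finite
differences serve as the independent oracle in the tests (agreement
≤ 1e−6 relative, in practice ~1e−9).

**Density solution.** The packing fraction is scanned over
[1e−10, 0.7404] (8 log-spaced + 52 linear nodes), sign changes of
P(η) − P are bracketed and polished by Brent's method to machine tolerance
(|P(ρ)−P|/P ≲ 1e−9).  The liquid branch returns the highest-density root,
the vapor branch the lowest; with multiple roots the returned state is
flagged stable/metastable by comparing ln ρ + a_res + Z across roots.
η ≥ 0.7405 raises a packing-fraction error rather than evaluating the
divergent hard-sphere term.

**Reference states.** Activity coefficients are mole-fraction scale with
the pure hypothetical liquid at the same T and P as reference:
γᵢ = φᵢ(T,P,x)/φ₀ᵢ(T,P).  For a solid solute below its melting point the
reference is the subcooled liquid, taken as the highest-density root; this
is the construction the solid–liquid equilibrium relation presumes.  Pure
reference fugacities are cached per (parameter set, component, T, P).
Osmotic coefficients follow as Φ = −ln(x_w γ_w)/(M_w m) with
M_w = 0.018015 kg/mol; pressure defaults to 101325 Pa throughout.

## Calorimetry reduction

* **Sample mass** (stage i): `m₀ = C_p/c_p` averaged over a window where
  matched heating and cooling curves agree; disagreement beyond 10%
  (configurable) raises a mass-loss error.  The reported relative mass
  uncertainty defaults to 11%, the established figure for chip-sensor mass
  determination.  A reference `c_p(T)` table for the crystalline solids
  ships as `data/cp_solid_synthetic.csv`; it is a *synthetic stand-in*
  with plausible magnitudes (≈1.3–1.9 J/(g K), 300–480 K) and should be
  replaced by measured values for quantitative work.
* **Peak onset and area** (stage ii): one straight baseline is fitted
  jointly to a pre-peak and a post-peak window (default 20 K wide,
  separated from the detected peak region by 5 K).  The onset is the
  intersection of that baseline with the tangent to the leading edge at
  its inflection point.  The derivative for the tangent is smoothed with a
  positive moving-average kernel over ≈1 K: a positive kernel cannot
  overshoot at sharp corners (a polynomial filter can, which biases the
  inflection search toward the apex), and at an inflection point the
  kernel's value bias vanishes to second order.  The area is the
  baseline-subtracted heat-flow integral over *time* (joules), taken
  between the baseline crossings so tails are not clipped.  Guards: no
  peak above 6 noise-σ prominence → error; a second peak within 50% of the
  dominant prominence → ambiguity error listing candidates.  The onset is
  invariant to baseline offsets and to unit rescaling.
* **Zero-rate extrapolation**: ordinary least squares of onset vs heating
  rate; the intercept is the thermodynamic melting temperature (the linear
  term absorbs thermal lag and superheating, so no per-scan lag model is
  applied).  Reported uncertainty: 95% two-sided Student-t × intercept
  standard error, combined in quadrature with any stated
  temperature-calibration uncertainty.
* **Molar fusion enthalpy**: peak area grows linearly through the origin
  with sample mass regardless of rate; the through-origin slope is the
  specific enthalpy (J/g), multiplied by the molar mass (89.1 g/mol
  l-alanine, 75.1 g/mol glycine, 18.015 g/mol water).  Uncertainty: slope
  standard error and the 11% mass uncertainty in quadrature — a
  standard-error approximation to the full instrument uncertainty budget,
  which typically lands the mass term in the dominant position.
* **Fusion entropy**: ΔS = ΔH/T_fus with first-order propagation.

## Synthetic-data generators

Generators are pure functions of seed and settings (bit-reproducible) and
emulate exactly the statistical structure the reduction assumes — and
nothing else:

* melting scans: apparent onset `T_fus + lag·β` plus Gaussian scatter
  (default 3 K), a peak whose baseline-subtracted area equals
  mass × specific enthalpy, a mildly tilted baseline, additive Gaussian
  noise (default 1% of peak height).  The peak is a Gaussian leading edge
  (width 3 K) with an exponential or Gaussian tail; for a Gaussian edge
  the tangent construction lands exactly 2 edge-widths below the apex,
  which is how the onset is planted analytically.  Defaults mirror a
  realistic chip-calorimetry campaign: rates 1000–10000 K/s, masses
  20–90 ng, onset lag of a few kelvin across the rate range.
* osmotic and solubility tables: forward-model values with planted kᵢⱼ or
  melting properties and multiplicative noise (≤3% for solubilities,
  matching typical experimental scatter).

Because noise is the only deviation from the forward model, recovery tests
are well-posed: they demonstrate solver correctness and uncertainty
calibration, *not* robustness to real-instrument artifacts (curved
baselines, partial decomposition, sensor drift), which are out of scope.

## Problem sizes and verification

The shipped study-scale recovery check uses 45 scans (9 rates × 5 scans,
~1900 points each) and 100 seeded replicates; joint coverage of the two
planted melting quantities by their reported uncertainties exceeds 90%.
Binary-parameter recovery uses 4–5 osmotic points per table; noiseless
recovery is exact to 1e−4 in kᵢⱼ.  All equilibrium computations are
two-component liquid states that solve in tens of milliseconds, so the
full suite runs in minutes on one CPU.

## Known limitations and open choices

* The published activity coefficient of l-alanine at saturation (0.244)
  is not exactly reproducible from the printed inputs: the printed fitted
  enthalpy (23.7 kJ/mol) together with the printed saturation composition
  implies γ = 0.240 through the equilibrium relation.  This implementation,
  using the standard term expressions stated above, computes γ = 0.2357 at
  that composition and a fitted enthalpy of 23.79 kJ/mol (0.4% from the
  printed fit); the corresponding glycine fit gives 21.07 vs the published
  21.0 kJ/mol.  The residual ~2% in γ is attributable to unstated
  implementation details of the original modelling code (e.g. the exact
  cross-association rule); sweeping the published variants moves γ by
  under 1% and not consistently for both solutes, so the standard rules
  are retained.
* No polar/electrolyte terms, no mixed solvents, no vapor–liquid flash, no
  glass-transition/cold-crystallization analysis, no heat-capacity
  difference in the equilibrium relation.
* Association cross rules other than Wolbach–Sandler, and onset
  constructions other than baseline∩tangent, are configurable only at the
  code level, not exposed as options.
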