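# Methods

## The additive relaxation model

The longitudinal relaxation rate of the [1-¹³C]pyruvate carboxylate carbon
is treated as a sum of statistically independent channels; each channel is a
closed-form function of the static field B₀ with a small number of physical
parameters.  Additivity is what makes the decomposition work: the pointwise
rate difference of two samples differing in one preparation feature equals
the toggled channel's rate curve, so each mechanism can be isolated and
fitted separately rather than in one ill-conditioned joint fit.

| channel | form | parameters (defaults) |
|---|---|---|
| background R₁⁰ | constant | 0.0044 s⁻¹ measured on the doubly deuterated sample |
| intraDD (methyl ¹H–¹³C) | constant | printed difference 0.0008 s⁻¹ (#B−#A) |
| interDD (solvent ¹H–¹³C) | constant | printed difference 0.0095 s⁻¹ (#I−#H); 0.0076 s⁻¹ variant (#E−#D) |
| PRE:O₂ | two-Lorentzian dispersion | amplitude 1/84.2−1/188.0 ≈ 0.00656 s⁻¹, τc = 6.1 ps |
| PRE:M⁺ (trace metals) | two-Lorentzian dispersion | 0.0133 s⁻¹ (H₂O) / 0.0113 s⁻¹ (D₂O), τc = 200 ps |
| PRE:radical (trityl) | two-Lorentzian dispersion | 0.002 s⁻¹, τc = 100 ps (both placeholders, fit-determined in use) |
| CSA | (2/15)(B₀Δσγ)²τc | Δσ = 136.5 ppm, τc = 7.3 ps |

Activation rules: degassing removes PRE:O₂; Tris and/or EDTA remove PRE:M⁺
(chelation or shielding — the model does not distinguish); radical filtering
/ ascorbate scavenging removes PRE:radical; solvent or methyl deuteration
divides the corresponding dipolar channel by
f = (I_H(I_H+1))/(I_D(I_D+1))·(γ_H/γ_D)² ≈ 15.914.

**Dipolar bookkeeping.**  The tabulated dipolar values are
protonated-minus-deuterated *differences* obtained by pair subtraction, and
the tabulated background was measured on the doubly deuterated sample, so it
already contains the deuterated dipolar residuals.  The registry therefore
reconstructs full protonated rates R_full = Δ·f/(f−1) and a pure background
R₁⁰ − ΣR_full/f, and the model then presents
`background_pure + R_full/(f or 1)` per channel.  This convention
simultaneously reproduces the tabulated values on both sides of every
toggle (e.g. #A → 1/0.0044 ≈ 227 s, #H at 1 mT → 43.4 s) and keeps the
invariant that toggling a deuteration feature rescales its channel by
exactly f.  A naive "divide the printed difference by f" on top of the full
background double-counts the residuals and misses the #A anchor by ~12%.

**PRE spectral density.**  The exact dispersion form used in the original
analysis is not published; we adopt a simplified Solomon–Bloembergen dipolar
form with fixed 3:7 weights on the nuclear and electron Lorentzians and a
single correlation time, A·[0.3·L(γ₁₃C B₀) + 0.7·L(γₑB₀)],
L(ω) = 1/(1+(ωτc)²).  It has exactly the two parameters the data constrain
(zero-field amplitude and τc), reduces to the amplitude at B₀ → 0, and its
dispersion is dominated by the electron Larmor frequency, which is the
physically relevant feature (the electron half-dispersion sits at
1/(γₑτc): ≈0.93 T for O₂ at 6.1 ps, ≈0.028 T for the metal term at 200 ps —
the "shoulder" below 0.1 T).  The electron gyromagnetic ratio enters by
magnitude only.  O₂ concentration is reported only when a molar relaxivity
is configured; the model constant required to convert amplitude to
concentration is not otherwise known.

**CSA.**  Extreme narrowing is assumed with no Lorentzian factor:
ω₁₃C·τc ≈ 5×10⁻³ at 9.4 T with τc = 7.3 ps, so the correction is
negligible.  Δσ and τc are not jointly identifiable from quadratic-in-B
data, so the rotational correlation time is always supplied (an MD-derived
value) and only Δσ (plus a field-independent baseline) is fitted — the fit
is linear in B².

**Exchange.**  The keto/gem-diol equilibrium (~10:1) exchanges fast
compared with relaxation, so observed rates are population-weighted means.
The registry rates are themselves observed (already-weighted) quantities;
the explicit weighting operation is provided for composing species-level
rates (e.g. MD-derived ones).

**Temperature.**  Only the two printed endpoint factors are implemented
(inter ÷2.6, intra ÷2.8 at 353 K vs 293 K); no interpolation is attempted.
The fully-deuterated dipolar-only limit computed from the MD rate constants
(0.0062 + 0.00068 s⁻¹, scaled by f) gives T₁ ≈ 39 min at 293 K.

## Estimation

* **Decay fits** are nonlinear least squares of S(t) = S₀·exp(−t/T₁)
  (optional constant offset behind a flag; off by default since thermal
  field-cycling data are difference-mode).  Uncertainties come from the
  Jacobian-based covariance.  Hyperpolarized series sampled with flip angle
  α every TR carry an extra per-pulse factor cos^(n−1)(α); the fitter
  removes the RF consumption rate −ln(cos α)/TR from the apparent rate.
  When the apparent rate does not exceed the RF rate, T₁ is unbounded by
  the data: the result is flagged rather than clipped.  As α → 0 the
  corrected fit coincides with the plain exponential fit.
* **Band statistics** are unweighted means ± sample SD over the points in
  three half-open field bands: low [5 µT, 8 mT), intermediate [0.1, 1) T,
  high [1, 10) T.  The exact band edges are not published; these follow the
  stated approximate ranges, and points in the 8 mT–0.1 T gap are excluded
  by default (configurable).  Single-point bands report SD 0 with a flag.
* **Subtraction** works pointwise on shared fields, or (optionally) after
  interpolating rates linearly in log₁₀B onto the intersection range.
  SDs propagate as σ_ΔR = √((σ_a/T₁ₐ²)² + (σ_b/T₁ᵦ²)²), which matches a
  10⁵-draw Monte-Carlo resampling within 5% for SDs up to 10% of T₁.
* **Weighting**: 1/σ² with σ from the propagated SDs; points lacking an SD
  get the profile's median SD; if no SDs exist the fit is unweighted and
  the covariance is scaled by the residual variance.  Whether the original
  fits were weighted is not stated; weighted is our default.
* **PRE fits** are grid-initialized over τc ∈ {1, 10, 100, 1000} ps with
  the best restart kept (lowest reduced χ², ties to the smallest τc); τc is
  fitted in picoseconds so both parameters are O(1) for the trust-region
  solver.  Flat data flag τc unidentifiable instead of failing.
* **Decomposition ledger** (`decompose_study`): background = low-band mean
  rate of the most protected sample (#A); intraDD from (#B,#A); interDD
  from (#E,#D); PRE:O₂ from (#D,#B); PRE:M⁺ from (#I,#F) and (#H,#D); CSA
  from #A's high-field (≥1 T) excess; the radical term from the residual of
  #G over the assembled radical-free model, fitted across all fields (a
  band mean would be biased by the Lorentzian dispersion).  Plan pairs must
  differ in exactly one composition feature; (#H,#D) is the one deliberate
  exception (no D₂O Tris-only sample exists) and carries an explicit
  override flag.  On noiseless synthetic data the ledger inverts the
  additive model exactly (≤10⁻⁶ relative on every parameter).

## Transport

Retained polarization along a trajectory B(t) is
exp(−∫dt/T₁(B(t))), evaluated by adaptive quadrature (relative tolerance
10⁻⁸, segment breakpoints passed explicitly).  B(t) is piecewise linear in
time; tabulated T₁(B) maps interpolate rates linearly in log₁₀B.  The
actual polarizer-to-magnet field map is installation-specific and not
published; the package ships a constant-low-field hold and a synthetic
three-segment ramp (1 mT → 1 T → 9.4 T) as examples and accepts user CSV
profiles.  The constant-field shorthand reproduces the closed-form anchors
(e.g. exp(−19.5/46.6) ≈ 66% for the standard sample over a short transfer).
Liquid-state polarization is quantified against a thermal reference
spectrum as (S_hyper/(S_thermal/n_scans))·tanh(ħγB/2k_BT), in percent.

## Synthetic data

The generator regenerates the study conditions: nine binary compositions
(#A–#I), a 25-point log-spaced grid over 7.8 µT–9.4 T, multiplicative
Gaussian noise of 3% on T₁ (with T₁_sd = noise·T₁), and hyperpolarized
decay series with additive Gaussian noise of SD noise·S(0).  A raw-decay
mode generates and re-fits a full thermal decay per field instead, for
end-to-end tests.  All randomness flows through explicit seeds
(package default 20260521).

What the generator does *not* emulate — and hence what passing tests do not
show about real data: the additive model is exact by construction (no
mechanism cross-terms, no exchange-rate field dependence), noise is
Gaussian and uncorrelated across fields, the field grid is idealized
(measured grids are irregular), and shuttle travel-time relaxation,
INEPT transfer efficiency and spectrometer noise spectra are absent.
Parameter-recovery results therefore validate the estimators, not the
physical completeness of the model.

Known closure gap: the tabulated component rates do not perfectly close the
measured profiles — summing them for plain water (#I) gives a low-field T₁
of ≈28.9 s vs the measured 30.9 ± 0.9 s, a ≈6% gap inherent to the source
values.  The test suite asserts this gap explicitly rather than hiding it.
The #H reconstruction closes to ≈0.03%.  The O₂ amplitude is stored as the
exact derived value 1/84.2 − 1/188.0 s⁻¹ rather than its 0.0066 rounding;
the metal-PRE τc (200 ps, "hundreds of picoseconds") and the radical
amplitude/τc are declared decisions, tagged as such in the registry
provenance map.

## Problem sizes and determinism

Default analysis sizes: 9 profiles × 25 fields, 10–20 seeded replicates for
recovery statistics, 10⁵ Monte-Carlo draws for the error-propagation
oracle, 10⁶-step Euler integration as the transport oracle.  These run in
seconds and are the package's chosen statistical scale; all are plain
function arguments.  Reports are byte-identical across reruns at a fixed
seed (sorted JSON keys, no timestamps).

## Limitations

* The radical channel has no published parameters; it is a fitted residual.
* Density-matrix spin dynamics, cross-correlated relaxation, scalar
  relaxation of the second kind and NOE are out of scope, as are vendor raw
  data formats and spectral processing (inputs are integrated amplitudes).
* The 0.0095 vs 0.0076 s⁻¹ interDD discrepancy between sample contexts is
  carried as a named variant, not resolved.
* Joint global fitting of all nine profiles in one likelihood is
  deliberately not implemented: the pairwise ledger mirrors how the
  measurements identify the mechanisms.
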