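# relaxcider

Mechanistic decomposition of [1-¹³C]pyruvate longitudinal relaxation across
magnetic fields, for hyperpolarized-MR physicists who need to understand —
and minimize — polarization loss between the polarizer and the scanner.

[1-¹³C]pyruvate is the workhorse probe of hyperpolarized metabolic MRI, and
its usable signal is limited by the longitudinal relaxation time T₁ of the
carboxylate ¹³C.  T₁ depends strongly on the magnetic field *and* on the
sample formulation (buffer, chelator, solvent deuteration, dissolved O₂,
DNP radical, pyruvate deuteration).  This package models the observed rate
as a sum of independent mechanism channels,

```
R₁(B₀) = R₁⁰ + R₁ᶦⁿᵗʳᵃᴰᴰ + R₁ᶦⁿᵗᵉʳᴰᴰ + R₁ᴾᴿᴱ:O₂(B₀) + R₁ᴾᴿᴱ:M⁺(B₀) + R₁ᴾᴿᴱ:ʳᵃᵈ(B₀) + R₁ᶜˢᴬ(B₀)
```

with

* **CSA** (chemical shift anisotropy), quadratic in field in the
  extreme-narrowing regime: `R₁ᶜˢᴬ = (2/15)(B₀·Δσ·γ₁₃C)²·τc`;
* **PRE** (paramagnetic relaxation enhancement) from O₂, trace metal
  cations, or trityl radical, as a two-Lorentzian dipolar dispersion
  `A·[0.3/(1+(γ₁₃C·B₀·τc)²) + 0.7/(1+(γe·B₀·τc)²)]` dominated by the
  electron Larmor frequency;
* field-independent **dipolar** channels (intramolecular methyl ¹H–¹³C and
  intermolecular solvent ¹H–¹³C), scaled by
  `(I_H(I_H+1))/(I_D(I_D+1))·(γ_H/γ_D)² ≈ 15.9` when the sites are
  deuterated;
* a lumped field-independent **background** (²H–¹³C residuals,
  spin-rotation, …).

Fast chemical exchange between the keto and hydrated (gem-diol) forms
averages the species rates with their ~10:1 populations,
`R₁ᵒᵇˢ = p_Py·R₁ᴾʸ + p_PyH·R₁ᴾʸᴴ`.

Because the channels are additive, subtracting the R₁-vs-B₀ (NMRD) profiles
of two samples that differ in a *single* preparation feature isolates one
mechanism, which is then fitted with its closed-form law.  The package
implements this decomposition, flip-angle-corrected fitting of
hyperpolarized decays, polarization-loss integration along field-time
trajectories, and a synthetic generator that regenerates the full
nine-sample study (#A–#I) from the tabulated component rates.

## Worked example

```python
from relaxcider import (GroundTruthRegistry, NINE_SAMPLES, generate_study_bundle,
                        decompose_study, total_r1)

registry = GroundTruthRegistry()                # tabulated component rates
print(1 / total_r1(1e-3, NINE_SAMPLES["H"], registry))   # 43.39 s at 1 mT
print(1 / total_r1(1e-3, NINE_SAMPLES["A"], registry))   # 227.3 s at 1 mT

bundle = generate_study_bundle(registry, seed=20260521)  # 9 profiles, 3% noise
res = decompose_study(bundle.profiles, registry_seeds=registry)
print(res.csa.delta_sigma)                      # ~138.6 ppm (truth 136.5)
print(res.pre_o2.params.amplitude_zero_field)   # ~0.00649 s^-1 (truth 0.00656)
```

The same workflow is laid out as numbered drivers under `analysis/`
(`01_simulate_study.py` … `05_transport_scenarios.py`), each writing its
tables under `results/`.  Running them in order prints, among others:

```
#A:  227.5 +/-  7.5 s (n=12)          # low-band mean of the most protected sample
#I:   29.2 +/-  0.6 s (n=12)          # plain water: ~8x faster relaxation
CSA             d_sigma 138.6 +/- 3.4 ppm  [136.5]
PRE:O2 (D-B)    0.00649 s^-1, tau_c 6.0 ps  [0.00656, 6.1 ps]
hold_1mT_19.5s: #G retains 63.5%, #C retains 90.4% -> SNR gain 1.42x
ramp_60s:       #G retains 27.5%, #C retains 69.3% -> SNR gain 2.52x
```

i.e. the decomposition recovers the injected mechanism parameters from the
noisy synthetic study, and optimizing the sample composition more than
doubles the polarization surviving a 60 s transfer.

A `relaxcider` CLI exposes the same steps
(`simulate | fit-decay | bands | subtract | decompose | transport | report`);
`relaxcider report` runs the pipeline end to end and writes a deterministic
JSON report.

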