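# qpmap — quantitative permeability mapping from diffusion-weighted ASL

`qpmap` estimates the blood–brain-barrier **water exchange rate k_W**
(min⁻¹), **cerebral blood flow CBF** (mL/100 g/min) and **arterial transit
time ATT** (s) jointly, voxel by voxel, from a multi-delay multi-b
diffusion-weighted arterial spin labeling (DW-ASL) difference-signal series.
It is aimed at perfusion-MRI researchers who want a transparent, fully
testable implementation of two-compartment permeability mapping — including
a digital phantom, so the entire pipeline can be exercised and validated
without scanner data.

## Model

Labeled arterial water arrives in the capillary bed after the transit time
ATT and crosses the blood–brain barrier into tissue at rate k_W. With
k = k_W/60, α = k + R₁ₐ, β = k/(k + R₁ₐ − R₁ᵦ) and t = δ + PLD, the
difference signal of one encode is

```
I  =  ΔM_b  +  (1 − sign(b)) ΔM_c

ΔM_b = 2 F ε M₀ (β/λ) [ e^{−(R₁ₐ−R₁ᵦ)ATT}/R₁ᵦ (e^{−R₁ᵦ(t−δ)} − e^{−R₁ᵦt})
                       − e^{−(R₁ₐ−α)ATT}/α   (e^{−α(t−δ)}  − e^{−αt}) ]
ΔM_c = 2 F ε M₀ e^{−(R₁ₐ−R₁ᵦ)ATT}/(λα) (e^{−α(t−δ)} − e^{−αt})
```

where F = CBF/6000 (mL/g/s), δ = 1.5 s is the labeling duration, ε = 0.6 the
combined labeling efficiency (0.8 labeling × 0.75 background-suppression
survival), λ = 0.9 mL/g the partition coefficient, and R₁ₐ = 0.6 s⁻¹,
R₁ᵦ the blood/tissue relaxation rates. Diffusion preparation (sign(b) = 1
for b ≥ 10 s/mm²) crushes the capillary term, so crushed and uncrushed
encodes separate the two compartments. The default protocol has 10 encodes:
b = 20 s/mm² at PLD = 1.0/1.5/1.8/2.0/2.5 s (NEX 3) and
b = 0/10/20/50/100 s/mm² at PLD = 1.2 s (NEX 1).

Maps are obtained by minimising, per voxel,

```
Σᵢ γᵢ² (Iᵢ − fᵢ(k_W, CBF, ATT))²  +  μ (k̃_W² + C̃BF² + ÃTT²)
```

with γᵢ = √NEXᵢ, tildes denoting division by nominal scales
(100, 50, 1.5), and μ either fixed or chosen by the L-curve method. The
solver is a bound-constrained damped Gauss–Newton iteration with monotone
(Armijo-accepted) steps, initialised at k_W = 0 with single-compartment CBF
and signal-weighted-delay ATT, plus a coarse grid presearch that guards
against local minima (details in `docs/methods.md`).

## Worked example

```python
from qpmap import (PhantomSpec, make_phantom, simulate_acquisition,
                   noise_sd_for_snr, default_protocol, FitConfig, fit_volume)
from qpmap.roi import roi_table

acq = default_protocol()
truth = make_phantom(PhantomSpec(seed=0))          # 20x20x10 digital brain
sd = noise_sd_for_snr(truth, acq, snr=100.0)       # difference-image SNR 100
series = simulate_acquisition(truth, acq, sd, seed=1)
res = fit_volume(series, truth.m0, truth.r1b, truth.mask, acq,
                 FitConfig(mu="auto", seed=0))
print(roi_table({"kw": res.kw_map, "cbf": res.cbf_map, "att": res.att_map},
                truth.labels, truth.names).round(2).to_string(index=False))
```

prints

```
 label       region    kw   cbf  att
     1       cortex 81.83 39.53 1.20
     2 white_matter 75.13 32.54 1.40
     3  hippocampus 81.38 37.66 1.28
     4          wmh 60.19 25.02 1.60
```

i.e. the fitted ROI means recover the generating truths (cortex
k_W = 81.51 min⁻¹, CBF = 39.60; white matter k_W = 75.19, CBF = 32.47;
lower k_W in the simulated lesion) to well under 1% at this noise level.
The same estimator is available in scikit-learn form
(`qpmap.fitting.PermeabilityFitter`, rows = voxels, columns = encodes), and
the `qpm` command line drives the pipeline from the shell
(`qpm simulate | fit | roi | cohort | pipeline`).

Beyond mapping, `qpmap.roi` provides the regional analysis used in cohort
studies: ROI means, WMH volume filtering (≥ 100 mm³) and NAWM masks,
nonparametric group tests (Wilcoxon signed-rank, Mann–Whitney,
Kruskal–Wallis with Dunn post-hoc), Pearson correlation, and multiple linear
regression of regional metrics on age (per decade), sex and vascular-risk
count, with added-variable plot data.

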