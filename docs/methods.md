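# Methods

## Signal model

The forward model is the two-compartment single-pass description of a
diffusion-weighted pseudo-continuous ASL difference signal. Labeled blood
water resides first in the capillary compartment (relaxing at the arterial
rate R1a) and is extracted into tissue (relaxing at R1b) at the exchange
rate k_W. Writing k = k_W/60 in s^-1, the compartment rates are
alpha = k + R1a and the extraction factor beta = k / (k + R1a - R1b);
signals are evaluated at t = delta + PLD with labeling duration delta.
A crushed encode (diffusion preparation, b >= b_crush = 10 s/mm^2) sees the
tissue compartment alone; an uncrushed encode sees the sum. Crushing is
binary — no intermediate IVIM-type attenuation is modeled, and b_crush is
configurable because the effectiveness of moderate b-values is a protocol
property, not a model constant.

Conventions worth stating explicitly:

- **Sign.** Difference signals are stored as nonnegative perfusion-weighted
  magnitudes: the model uses a +2 prefactor with the bracket ordered so that
  physiologic parameters give signals >= 0. The inversion consumes
  magnitudes; a signed label convention would only flip both data and model.
- **Units.** k_W is carried in min^-1 and CBF in mL/100 g/min at every
  interface; conversion to s^-1 and mL/g/s happens once, inside the forward
  model. PLDs are milliseconds in protocol files and seconds in memory (one
  conversion point, in the protocol reader).
- **Capillary relaxation.** The capillary term carries the factor
  e^{-(R1a-R1b) ATT} exactly as the model is specified, even though a pure
  R1a decay might be expected on physical grounds; this keeps the
  implementation faithful and the factor is isolated in one function should
  a correction ever be warranted.
- **Degenerate beta.** beta is singular where k + R1a - R1b = 0
  (k_W = 60(R1b - R1a), about 10 min^-1 for cortical values). The full
  signal has a removable singularity there; within 1e-9 s^-1 of the
  degeneracy beta is evaluated with R1a perturbed by 1e-6 and a warning is
  emitted. The perturbation error is confined to a parameter interval of
  width ~6e-8 min^-1 and is irrelevant at physiologic k_W.
- **Large-k_W limit.** e^{k ATT} is never formed alone; it is folded into
  combined exponents so that the k -> infinity limit underflows to the
  single-compartment (beta = 1) form instead of producing inf * 0. The
  approach to that limit scales as (R1a - R1b) * 60 / k_W, which is what the
  limit tests assert.

## Inversion

Each voxel minimises

    sum_i gamma_i^2 (I_i - f_i(kW, CBF, ATT))^2 + mu (kW~^2 + CBF~^2 + ATT~^2)

with gamma_i = sqrt(NEX_i) — averaging NEX excitations reduces noise SD by
sqrt(NEX), and gamma weights residuals by inverse noise SD (a gamma = NEX
override exists). Tildes denote division by the nominal scales
(100 min^-1, 50 mL/100 g/min, 1.5 s): a single mu is only meaningful if the
three parameters live on a common scale. The penalty is applied per voxel;
for a separable ridge this is identical to penalising the map norms.

Bounds are kW in [0, 500] min^-1, CBF in [0, 200] mL/100 g/min, ATT in
[0.3, 3.0] s. Initialization: k_W = 0; CBF from the consensus
single-compartment quantification of the encode nearest PLD = 1.5 s
(zero when the difference signal is nonpositive); ATT as the
signal-weighted mean PLD over the crushed encodes (duplicate PLDs averaged
first, weights clamped at zero, result clamped to the sampled PLD range,
midpoint fallback when all weights vanish).

**Solver.** The minimiser is a projected Levenberg–Marquardt iteration in
the nondimensionalized coordinates: the damped Gauss–Newton system
(H + lam diag(H)) d = -g is solved per voxel (3x3), the step is clipped to
the box, and accepted only under an Armijo decrease condition; rejection
inflates the per-voxel damping and retries. At high damping the step
degenerates to a scaled gradient descent step, so the method spans the
gradient-descent-to-Newton continuum while keeping descent strictly
monotone. Iteration stops when every nondimensionalized parameter changes
by less than rel_tol = 0.01 relative to max(|value|, 0.01) in one accepted
step, or after max_iter = 100 iterations. Plain first-order descent was
evaluated first and rejected: on this cost surface it stalls far from the
optimum within the iteration budget, and the surface genuinely contains
local minima — long-transit voxels produce negative short-PLD model values,
which creates a spurious KKT corner at CBF = 0. To make the inversion
globally reliable, a deterministic coarse presearch evaluates an
8 x 9 (k_W, ATT) grid with the CBF axis solved in closed form (the model is
linear in CBF, so the ridge-optimal CBF per node is a quotient of weighted
inner products); Levenberg–Marquardt is run both from the standard
initialization and from the best presearch node, and the lower-cost solution
wins (ties go to the standard initialization). On noiseless voxels this
recovers truths to ~1e-5 relative and matches an exhaustive grid oracle.

All solver state (damping, convergence, iteration count) is per voxel and
no randomness is involved, so fitting a volume is bit-identical to fitting
each voxel alone, independent of storage order, and reproducible.

**Regularization selection.** With mu = "auto", fits are repeated over a
log-spaced mu grid (default 1e-4 to 1e2) on a seeded subsample of up to 500
masked voxels; the (log residual norm, log solution norm) pairs form the
L-curve and the mu of maximal Menger curvature is returned (ties toward
smaller mu). At high SNR the low-mu branch of the curve is nearly flat and
the selected mu is correspondingly small — which is the correct reading of
the trade-off there, since stronger shrinkage only degrades the fit.

## Digital phantom

The phantom is a brain-like concentric geometry on a small grid (default
20 x 20 x 10 voxels of 1.9 x 1.9 x 4 mm): an ellipsoidal brain whose outer
rim is cortex and core is white matter, with an ellipsoidal hippocampus and
a white-matter-lesion blob embedded. Regional ground-truth means default to
the published cohort values for this technique — cortex k_W 81.51 min^-1 /
CBF 39.60; white matter k_W 75.19 / CBF 32.47 — with R1b 0.77 s^-1 (cortex)
and 1.15 s^-1 (white matter), typical 3 T tissue rates, since per-subject
R1b maps are acquisition inputs rather than published constants. ATT values
(1.2–1.6 s) and the hippocampus/lesion parameters are representative
physiologic choices; the lesion carries reduced k_W and CBF, mirroring the
reported direction of WMH effects. Within-region spread is
truncated-normal per voxel (defaults: SD 4 min^-1 for k_W, 2 for CBF,
0.05 s for ATT), modest enough that ROI means are estimated from
~10^2–10^3 voxels with negligible sampling error.

Acquisition simulation evaluates the forward model and adds Gaussian noise
with SD noise_sd / sqrt(NEX_i) per encode: on difference images at high
SNR, the difference of two Rician magnitudes is approximately Gaussian, and
a Rician option is deliberately omitted. "Difference-image SNR" is defined
as (mean cortical signal of the crushed b = 20, PLD = 1.5 s encode) /
noise_sd at NEX = 1; the reference experiments use SNR 100.

What the phantom does **not** emulate: anatomically realistic geometry,
partial-volume mixing at tissue boundaries, motion and physiological noise,
spatially varying M0/coil profiles, and dispersion of the labeled bolus.
Passing the recovery tests therefore demonstrates correctness of the
model-inversion chain under the stated noise model, not robustness to the
full range of in-vivo confounds.

The cohort generator draws age uniformly on 25–85 years, sex
Bernoulli(0.37, female = 1), and vascular-risk counts 0–3 with
probabilities (17, 5, 5, 3)/30, matching the reference cohort's margins;
the regional outcome follows intercept 95 + slope(-4.43 per decade) x
age/10 + risk effect (-3 per factor, the reported direction) + N(0, 8).
An optional WMH block adds a lognormal lesion volume and a lesion k_W that
declines with log volume, for exercising the correlation analysis.

## Regional and cohort statistics

ROI means are arithmetic means over labeled voxels; non-finite voxels are
excluded and counted in the log. WMH masks are resampled with trilinear
interpolation and re-binarized at the 0.5 probability level; subjects enter
WMH analyses only when lesion volume is >= 100 mm^3 (inclusive threshold);
NAWM is white matter minus WMH. The published regional analysis keeps WMH
voxels inside the white-matter ROI, so that is the default here too, with
NAWM available separately.

Group comparisons are two-sided nonparametric tests (scipy): Wilcoxon
signed-rank for paired regions (exact null enumeration for n <= 12, zero
differences dropped per standard practice, configurable), Mann–Whitney U
for independent groups, Kruskal–Wallis across more than two groups followed
by Dunn's rank-sum z tests with tie correction and Bonferroni adjustment
over the pairwise comparisons (the adjustment choice is ours; no post-hoc
method was specified). Pearson correlation uses the standard two-sided
t-approximation. The regional regression is OLS (statsmodels) of a regional
metric on age/10, sex and risk count, so the age coefficient reads
"per decade"; added-variable data are produced by Frisch–Waugh
partialling, whose slope equals the multiple-regression age coefficient
exactly (asserted numerically in the tests). Significance is read at 0.05.

## Problem sizes and tolerances in the tests

The reference recovery experiment uses the 20 x 20 x 10 phantom
(~1450 brain voxels) at SNR 100 — large enough that ROI means are stable to
well under the 5% acceptance band, small enough that the full suite runs in
well under a minute of fitting time. The gradient check compares analytic
and central-difference gradients (h = 1e-4 x scale) to 1e-4 relative; the
grid-search oracle covers k_W 0–200 step 1, CBF 0–100 step 0.5, ATT
0.5–2.5 step 0.01, evaluated exactly with the CBF axis expanded
quadratically. The type-I-error test checks 2-SE coverage over 200 seeded
replicates against its binomial sampling band rather than a point value.

## Known limitations

- Voxels are fit independently; spatially coupled regularization (e.g.
  total variation) is out of scope, as are uncertainty maps.
- The model is binary in crushing and single-pass in kinetics; venous
  outflow, bolus dispersion and magnetization transfer are not modeled.
- The single-compartment CBF initializer ignores exchange and is biased at
  finite k_W; it only seeds the solver, which removes the bias.
- The relative-change stopping rule can flag a voxel converged at a flat
  KKT corner; the presearch start makes this rare, and such voxels are
  visible through their elevated final cost.
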