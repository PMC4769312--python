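# Methods

`neuropet` implements a desk-scale, fully testable version of a
semi-automated multimodal neuroimaging workflow: quantitative cerebral
blood flow (CBF) mapping from dynamic ¹⁵O-water PET, relative-perfusion
mapping from early-phase ¹⁸F-FDDNP PET, rigid and diffeomorphic spatial
normalization, atlas-driven ROI extraction and agreement statistics — all
exercised on a synthetic digital phantom rather than patient data.  This
note records the models, the numerical choices, and what the phantom does
and does not emulate.

## Kinetic models

**One-tissue water model.**  Tissue activity follows
`dC_T/dt = K1·C_b(t) − k2·C_T(t)` with the measured voxel signal
`C_ROI = C_T + Vb·C_b`.  K1 (mL/mL/min) is the delivery rate constant,
proportional to flow; k2 (1/min) the clearance constant; Vb the fractional
vascular volume.  CBF in mL/100 g/min is `K1/E × 100` with the first-pass
extraction fraction E = 0.85 by default (configurable; E = 1 returns raw
K1 in per-100 g units, and the K1 map is always retained alongside CBF).
Density is taken as 1 g/mL.

All convolutions run on a uniform fine grid (0.01 min step) with the input
treated as piecewise linear; the exponential convolution then has an exact
per-step recursion (evaluated as a first-order IIR filter), so model
curves agree with a stiff ODE integration to ~1e-8 relative.  Blood curves
are linearly interpolated, zero before the first sample.  Frame values are
the time-average of the continuous curve over each frame, computed exactly
for the piecewise-linear interpolant.  Fit weights are proportional to
frame duration (longer frames collect more counts); this is the standard
first-order surrogate when reconstruction variance is unavailable.

**Voxel fitting.**  `fit_one_tissue` exploits that the model is linear in
(K1, Vb) at fixed k2: k2 is profiled over a coarse logarithmic grid with a
linear solve at each node, and the three best candidates seed bounded
trust-region least-squares polish runs.  Noiseless frame-averaged TACs are
recovered to ~1e-13 relative.

**Delay and dispersion.**  The arterial curve measured at the sampling
site lags (delay Δt) and is smeared (monoexponential dispersion, time
constant τ) relative to the input the brain sees.  Both are estimated by
exhaustive grid search, Δt ∈ [−10, 20] s in 0.25 s steps × τ ∈ [0, 20] s
in 0.5 s steps, against the whole-brain frame TAC.  Each candidate shifts
the measured curve and applies the closed-form inverse of the dispersion
kernel, `c(t) = m(t) + τ·m′(t)` (exact for a monoexponential kernel on the
fine grid — no numerical deconvolution), then scores the candidate by the
weighted residual of the exact frame-averaged one-tissue fit with k2
profiled out.  Scoring in the frame-averaged model domain matters: schemes
that disperse the data side, or that linearize using a continuous curve
re-interpolated from 26 frame values, systematically shift the noiseless
argmin by several grid steps.  A known (6 s, 5 s) degradation is recovered
exactly on the grid from a noiseless whole-brain TAC.

**Ridge mapping with a spatial constraint.**  Whole-image maps use the
integrated (operational) form `C_ROI = P1·∫C_b − P2·∫C_ROI + P3·C_b` with
P1 = K1 + k2·Vb, P2 = k2, P3 = Vb, all regressors frame-averaged; the
per-voxel ∫C_ROI uses the piecewise-linear interpolant of that voxel's
frame TAC, applied as one precomputed frame-to-frame linear operator so
the whole image is a batched 3×3 solve.  The exact formulation of the
spatial constraint in the original ridge proposal is not reproduced here;
the package's own choice is a second pass shrinking each voxel toward the
Gaussian-smoothed first-pass maps (FWHM 2 voxels) with per-voxel,
per-parameter penalty `h = wrss / (local variance + ε)`.  This reduces to
the unpenalized estimator as h → 0, and on a spatially constant truth with
5 % noise it roughly halves the voxel-wise RMSE of all three parameters
with regional mean bias below 1 %.

**SRTM basis functions.**  The simplified reference tissue model
`C_T = R_I·C_R + (k2 − R_I·θ)·(C_R ⊗ e^{−θt})`, θ = k2/(1+BP), is fitted
by the basis-function method: θ fixed on a grid of 100 values log-spaced
between 0.00636 and 1 min⁻¹, per-θ weighted linear solves for
(α1, α2) = (R_I, k2 − R_I·θ), minimum-wrss selection with ties going to
the smaller θ.  α2 is unconstrained, so negative k2/BP estimates are
reported rather than clipped, and degenerate designs are flagged.  When
the reference TAC is the frame-sampled curve itself its measured values
are used directly as the reference column (the estimator is then exact on
self-referential data); basis curves always come from the fine-grid
interpolant.  Note one structural limit: when R_I = 1 + BP, α2 = 0 and θ
drops out of the model entirely, so θ is unidentifiable there by
construction (R_I is still recovered exactly).

The early-summed FDDNP image (0–6 min integral, mid-frame-in-window rule)
divided by its cerebellar-gray mean gives the R_P map; nCBF is the CBF map
divided by its cerebellar-gray mean.

## Registration

**Rigid.**  6-parameter (3 in 2-D) alignment by Powell optimization of
−MI (32-bin joint histogram, nats) on a 4/2/1 pyramid, warm-started
across levels.  A lesion mask on the fixed image can be supplied: the
interior is zeroed before pyramid smoothing and any voxel whose smoothed
value has lesion contribution is excluded from the histogram, making the
result exactly independent of lesion-interior intensities.  Extending the
missing-data treatment to the rigid stage (not only the normalization) is
this package's choice; it is what makes the whole chain invariant.

**Symmetric diffeomorphic (greedy).**  Two half-way warps φ1 (on S) and
φ2 (on T) meet at a midpoint.  Per iteration: localized squared
cross-correlation (window radius 4 voxels, local means subtracted; the
analytic intensity derivative is validated against finite differences to
1e-3) gives gradients on both half-warped images; each is smoothed with a
fluid Gaussian (σ = 3 voxels), scaled so the largest update is 0.25 voxel,
composed into its half-warp; the total fields are smoothed elastically
(σ = 0.5 voxel).  A candidate iteration is accepted only if the metric
does not decrease (otherwise the step is halved), so the recorded metric
trace is non-decreasing within a level, and any non-positive Jacobian also
halves the step.  Four resolution levels (8/4/2/1), at most 250 iterations
each, early stop when the score gains < 1e-6 over 10 iterations.  At
convergence the full forward map is φ2⁻¹∘φ1 and the inverse φ1⁻¹∘φ2;
inverses come from fixed-point iteration (mean residual ≤ 0.01 voxel).
The greedy scheme replaces full time-integrated velocity-field
optimization: the geodesic energy is never evaluated numerically, and the
linear-operator regularization is approximated by the two Gaussians.  The
window radius and smoothing constants are package defaults, chosen for
the 128² phantom scale; all are configurable.

Constrained cost-function masking treats a focal lesion as missing data:
lesion voxels of S are zeroed and excluded from every correlation window,
the metric gradient is forced to zero inside, and the update field inside
the (warped) mask is filled by diffusion inpainting — nearest-exterior
seeding followed by neighbor-average relaxation with the exterior held
fixed — giving a smooth extension of the surrounding velocity.  Because
the interior never influences any computed quantity, registration output
is bit-identical under arbitrary changes of lesion-interior intensities.

Transforms compose by concatenation into a single displacement field
(point path listed from the output grid inward), so an image or atlas is
interpolated exactly once; fields are stored as voxel-unit displacements
of their grid.  Registration contains no randomness.

## Atlas ROIs and statistics

Labels propagate by nearest-neighbor pull-back through the concatenated
chain (template → structural → PET); no partial-volume weighting.  Region
TACs are unweighted voxel means per frame.  Regional statistics are
mean/SD (n−1)/count per named label group; the whole-brain gray matter
composite is the unweighted mean of the gray-matter region means (an
average of averages, not voxel-pooled).  Bland–Altman agreement uses
first-minus-second differences and mean ± 1.96·SD limits; CV% is
100·SD/mean of subject-level regional means.

## The phantom

The generator emulates every input the pipeline consumes: a concentric-
ellipse "brain" (cortical shell split into four lobar sectors, two
subcortical blobs, ventricle, cerebellar gray patch, white-matter core)
with per-region intensities, bias field and noise for the structural
image; a gamma-variate arterial input with recirculation tail; dynamic
frames produced by the same forward-model evaluators the estimators
invert (the simulation and fitting paths share only the model evaluators,
never the estimators); seeded smooth deformations with guaranteed
positive Jacobian and grid landmarks; ellipsoidal lesions; and degraded
blood curves.  Dynamic noise is proportional Gaussian with
σ = noise% · value · √(d_max/d_f), the first-order count-statistics
behavior of reconstructed images — no projection-domain Poisson, PSF,
scatter or motion is simulated, so passing tests demonstrate estimator
correctness and pipeline integrity, not robustness to real scanner
physics.

Default kinetics encode gray flow 33, cerebellar gray 38.4 and white
20 mL/100 g/min at E = 0.85 (K1 = 0.2805, 0.3264, 0.17 min⁻¹; k2 = K1/0.9,
partition coefficient 0.9 mL/g), FDDNP relative deliveries 0.55–1.0 with
small binding potentials, and a single-compartment reference region.  The
default study uses the 26-frame 10-min water protocol, the 20-frame
65-min FDDNP protocol and 5 % frame noise.  The blood curve consumed by
the delay/dispersion demonstration is sampled on the fine grid (emulating
continuous detector sampling); with only the 15 hand-drawn samples the
piecewise-linear interpolation error is on the order of the wrss
differences between adjacent 0.25-s candidates.

The bundled end-to-end scene: the phantom at rest serves as template; the
subject structural image is the template pushed through a known smooth
deformation (default max 5 voxels) plus a bright focal lesion; the
dynamic scans live on a grid rigidly shifted by (3, −2) voxels.  Problem
sizes throughout are 128² in 2-D (32³ for the 3-D checks), chosen so the
full dual-tracer pipeline completes in well under a minute on one CPU
while every estimator still operates far from its trivial regime.

## Known limitations

- The spatial-constraint ridge is this package's formulation of an
  under-specified idea; other shrinkage targets are defensible.
- The greedy symmetric scheme approximates, not implements, geodesic
  optimization; symmetry holds to ~0.06 voxel empirically, not exactly.
- Regional means from propagated labels carry boundary-voxel bias of a
  few percent (mislabeled edge voxels mix neighboring tissue values);
  this is inherent to nearest-neighbor atlas propagation and visible in
  the phantom's gray/white ratio (≈1.60 recovered vs 1.65 generated).
- Decay correction, partial-volume correction and two-tissue models are
  out of scope; inputs are assumed decay-corrected.
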