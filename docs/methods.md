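# Methods

## Model and scope

Tissue susceptibility χ (ppm) perturbs the static field; sampled on a voxel
grid the perturbation along B₀ is `f = F⁻¹[D·F[χ]]` with the unit dipole
response `D(k) = 1/3 − k_b0²/|k|²`, `D(0) = 0`, built on physical
frequencies so anisotropic voxels are handled. The measured quantity is the
phase of a single-echo gradient-echo acquisition, `φ = c·f` with
`c = 2π·γ̄·B₀·TE` (γ̄ = 42.577 MHz/T; defaults TE = 19 ms, B₀ = 7 T, so
c ≈ 35.58 rad/ppm). The package reconstructs χ from two complex acquisition
averages and carries the result into parcel-wise case-control statistics.
Everything runs on synthetic data with known ground truth; no claim is made
about scanner-specific effects the phantom does not model (see
*Limitations*).

## The phantom and what it does and does not emulate

`default_phantom_spec(n)` builds a spherical "head" mask (radius 0.42·n)
containing a central zero-susceptibility ventricle (the reference region)
and three spherical regions at +0.10, −0.05 and +0.05 ppm, each with its own
piecewise-constant magnitude level so magnitude edges coincide with
susceptibility edges (the assumption morphology-enabled inversion relies
on). The forward simulation is exact dipole physics:

* tissue field by FFT convolution with D (the same operator the inversion
  uses, so round-trip errors isolate the *inverse* problem);
* background field from point dipole sources placed ≥ 10 voxels outside the
  mask, evaluated with the closed-form response
  `amp·(3cos²θ−1)/(4πd³)` in real space — FFT-generated source fields are
  circularly aliased and are *not* sampled harmonic functions, which
  spuriously breaks the mean-value property V-SHARP depends on;
* a smooth harmonic polynomial (shim-like) background plus a separate
  *non-harmonic* low-order polynomial (amplitude 0.01 ppm) emulating
  residual transmit-field phase that survives V-SHARP and is the target of
  the polynomial detrend;
* noise: each average is `mag·e^{icf}` plus independent complex Gaussian
  noise of SD (reference magnitude 1)/SNR per channel; the second average
  additionally carries a global 0.5 rad instrumental phase offset that the
  phase-matching stage must remove. Default SNR 100.

Not modeled: realistic anatomy, coil sensitivities, EPI distortion, k-space
sampling, motion, flow, or chemical shift. Passing tests therefore
demonstrate correctness of the reconstruction mathematics and statistics
pipeline under ideal geometry — not robustness to the full phenomenology of
in-vivo 7 T data.

## Reconstruction stages and numerical choices

**Phase matching.** The global offset is
`φ₀ = angle(Σ_mask avg2·conj(avg1))` (maximum-likelihood for a single
offset); the complex mean follows.

**Brain mask.** Threshold at 0.4 × the 99th-percentile magnitude, keep the
largest 26-connected component, fill holes.

**Unwrapping.** Best-first region growing over the 26-connected in-mask
graph with edge reliability `min(q_a, q_b)/(|Δφ_wrapped| + 10⁻³)`, quality
q = magnitude. Pure voxel-quality ordering takes diagonal steps whose true
phase difference can exceed π (×√3 of the per-voxel gradient) and seeds 2π
errors on steep smooth fields; ranking *edges* by wrapped difference crosses
steep shells only along their mildest links, and measured zero wrong 2π
multiples on the steep-bump benchmark (peak 25 rad, σ = 8 voxels, SNR 20,
10 seeds). The global 2π ambiguity is fixed by subtracting
`2π·round(median(φ)/2π)`.

**Per-average fields.** Each average differs from the combined volume by
sub-wrap noise plus a global offset, so the per-average field maps used for
noise estimation are `f ± wrap(φ_avg − φ_combined)/c` with the mask-mean
offset removed — no second unwrap.

**Weight map.** SD estimate `s = |f₁ − f₂|/√2`, floored at (1st in-mask
percentile)/100 (the floor only guards 1/s; a floor at the raw percentile
would hide genuinely low-noise voxels from the outlier rule). Weights
`w = 1/s` above `median + 3·IQR` are replaced by the 3³ boxcar mean of
unflagged neighbors; W is normalized to max 1. The pipeline additionally
pools s² over a 3³ neighborhood (27 df): the pointwise single-difference
estimate is so heavy-tailed that unpooled weights measurably degrade the
inversion (region medians from ≈ −3 % to ≈ −16 % on the noiseless phantom).
The unpooled form remains the function's default.

**V-SHARP.** Spherical-mean kernels with anti-aliased (clipped-linear)
boundary weights at radii 6→1 voxels (scaled by voxel size; configurable in
mm); per voxel the largest kernel whose support stays in the mask, erosion
computed by FFT; deconvolution of `(δ − S_rmax)` by truncated division
(cutoff 0.05). Anti-aliased kernels matter: hard-indicator balls leave ~5 %
discretization residual on harmonic fields, the anti-aliased ones < 0.1 %.

**Polynomial detrend.** Degree ≤ 4 least squares over the eroded mask,
coordinates centered and scaled for conditioning. The pipeline uses the
dipole-aware form: the polynomial is fitted to `f − d∗χ_TKD` (χ_TKD a
truncated-kernel division inversion, cutoff 0.1) rather than to f itself,
because tissue dipole fields project substantially onto low-order
polynomials over a convex mask and the plain fit removes real signal — on
the phantom the plain fit biased region medians by up to −26 % after
inversion, the dipole-aware fit by < 10 %. The plain form (exact
annihilation, idempotence) is the function's default and is what the
standalone CLI stage applies.

**MEDI.** Minimizes `λ‖W(e^{icd∗χ} − e^{icf})‖² + ‖M_G∇χ‖₁` over χ
supported on the mask, on a grid zero-padded by 20 voxels per side. λ = 200
follows the toolbox convention in which the optimization operates on
phase-scale susceptibility; on the ppm-scale objective implemented here that
is λ/c. M_G exempts the top 95 % of in-mask gradient entries of the
magnitude (edges penalize nothing; the remaining 5 % carry unit penalty);
the ℓ₁ is smoothed with ε = 10⁻⁶ ppm². Solver: Gauss–Newton with IRLS
reweighting of the gradient term, CG inner solves (8 iterations, tol 0.01),
backtracking line search (objective never increases), stop at relative
update < 5·10⁻³ or 30 outer iterations.

**Model-error tuning.** Voxels whose data-fidelity residual exceeds
6 × the in-mask median have W divided by (residual/median), capped at 100;
rounds repeat until no new voxel is flagged, the new-flag count stops
shrinking, or 5 rounds; then a final full solve runs. Residuals are
screened on a *probe* solve with edge fraction 0.5 and 8 Gauss–Newton steps:
under the production 95 %-edge setting the effectively unregularized solver
absorbs localized model error into χ, leaving no residual signature (a
corrupted voxel was detectable in only 7/20 runs from the converged
production solve, versus 20/20 from the probe, with 1–4 total flags).
Residuals below 10⁻⁶ rad are treated as numerically zero. Tuning is off by
default in the pipeline; with weights estimated from a single average pair,
weight-estimation noise itself produces heavy residual tails that the
median rule would flag wholesale.

**TGV comparator.** `α₁‖∇χ − v‖₁ + α₀‖E(v)‖₁ + ½‖d∗χ − f‖₂²` solved by
Chambolle–Pock (steps 1/√32, over-relaxation 2x_{n+1} − x_n), the data prox
in closed form in k-space. Defaults α = (2·10⁻⁴, 1·10⁻⁴) ppm, 600
iterations: on the noiseless phantom weaker α admits magic-angle streaking
and stronger α shrinks small regions; this setting keeps region medians
within ~10 % while remaining a genuinely different regularization family
from MEDI.

**Referencing and parcels.** χ minus the mean over the ventricle label
(intersected with the eroded mask); parcel means over label ∧ eroded mask,
parcels with no surviving voxels reported missing (NaN), never zero.

## Cohort and rater simulators

Cohorts default to 80 patients + 50 controls; ages Uniform(18, 72), sex
Bernoulli(0.5) coded 0/1, onset side right with probability 29/80 for
patients. Parcel values are baseline + effect·1[patient] + β_age·age +
β_sex·sex + N(0, 0.01 ppm), with effects (default 0.02 ppm in 10 of 100
homologous-pair parcels) injected *ipsilateral to the onset side*, which the
left–right flip subsequently aligns — with side-independent effects the
flip would smear half of each effect onto the homologue and guarantee false
positives, making the downstream recovery analysis incoherent. Scores are
linear in the (centered) designated parcel values plus noise, on a
mean-100/SD-10-like scale. Raters: each participant has a latent label set
over 2 hemispheres × 4 lobes (two labels with probability 0.2); each of 5
raters reproduces it with probability `fidelity` (default 0.8), otherwise
draws one uniform label.

## Statistics

Per parcel, OLS of susceptibility on age, sex and the predictor (group coded
1 = patient, or a score), complete cases per parcel; predictors are never
standardized so β is in ppm. BH step-up FDR with rejection at adjusted
p < q (q = 0.01); Glass' Δ = (mean_patients − mean_controls)/SD_controls;
post-hoc power = P(F′(k, n−k−1, ncp) > F_crit) with `ncp = n·R²/(1−R²)`.
Krippendorff's α uses the coincidence accounting over units with ≥ 2
ratings and a *set* distance (0 iff the two label sets intersect, else 1) —
a non-standard but internally consistent extension matching the lenient
pairwise partial-overlap agreement; for single-label data it reduces to the
nominal α exactly (cross-checked against a brute-force implementation).
Under the global null the realized FDR reduces to the probability of any
rejection, which BH controls at q.

## Problem sizes

Validation experiments run at the sizes the accompanying tests and
acceptance script use: 128³ for the closed-form sphere check, 64³ for
V-SHARP and the full MEDI/TGV round trip (padded to 104³), 48³ for the
unwrapping benchmark, 32³ (padded 48³) × 20 replicates for the model-error
experiment, and 200/50 replicates for the FDR/recovery calibrations. These
choices keep a full validation run around ten minutes on one CPU while
leaving every conclusion (suppression fractions, round-trip errors,
calibration rates) stable with respect to grid size in spot checks.

## Known limitations

* Single orientation, single echo; no COSMOS-style multi-orientation
  disambiguation of the dipole null space.
* The phantom's piecewise-constant magnitude makes the edge set ideal;
  in-vivo edge masks are noisier and the 95 % edge fraction correspondingly
  less forgiving.
* The two-average noise-SD estimate is intrinsically 1-df; the pooled
  variant trades noise-map resolution for stability. A magnitude-based
  (1/SNR) weight map is the documented fallback when only one average
  exists.
* Model-error tuning is validated for isolated corrupted voxels against
  calibrated weights; vessel-like extended model error is not simulated.
* The inter-rater metrics are validated against their definitions and a
  brute-force oracle, not against any clinical rating table.
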