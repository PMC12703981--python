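# ferromap

Quantitative susceptibility mapping (QSM) reconstruction and parcel-wise
group statistics for high-field gradient-echo MRI, exercised end-to-end on a
synthetic dipole-physics phantom and simulated case-control cohorts.

QSM estimates tissue magnetic susceptibility χ (in ppm) — in the brain a
proxy for iron deposition — from the phase of a gradient-echo acquisition.
The field perturbation along B₀ relates to χ through convolution with the
unit dipole response, in the frequency domain

```
f(k) = D(k) · χ(k),      D(k) = 1/3 − k_z² / |k|²,      D(0) = 0,
```

which vanishes on the magic-angle cone and makes the inversion ill-posed.
`ferromap` implements the full single-echo 7 T chain used in interictal
epilepsy imaging:

1. **Phase matching and averaging** of two complex acquisition averages;
2. **Brain masking** (fractional-intensity threshold 0.4, largest component);
3. **3-D path-based phase unwrapping** (best-first region growing guided by
   edge reliability);
4. **Noise weighting** from the disagreement of the two averages;
5. **V-SHARP** background-field removal (variable spherical-mean kernels,
   truncated deconvolution) plus 4th-order polynomial detrending of residual
   transmit-field effects;
6. **Morphology-enabled dipole inversion (MEDI)** — nonlinear fidelity
   `λ‖W(e^{icd∗χ} − e^{icf})‖²` with an edge-masked L1 gradient penalty
   (λ = 200, 95 % edge voxels, [20 20 20] zero padding) — with optional
   model-error tuning (MERIT-style residual down-weighting), and a **TGV**
   comparator inversion;
7. **Zero-referencing** to a ventricle region and **parcel aggregation**;
8. **Statistics**: per-parcel OLS with age/sex covariates and a group or
   score predictor, Benjamini–Hochberg FDR (P < 0.01), Glass' Δ, post-hoc
   power from the noncentral F distribution, left–right flipping of
   right-onset subjects, z-maps against controls, Bland–Altman method
   agreement, and inter-rater reliability (pairwise partial-overlap
   agreement and Krippendorff's α with a label-set distance).

Raw clinical MRI for such studies is typically not redistributable, so the
package ships a first-class synthetic-data module: a geometric susceptibility
phantom with forward-simulated wrapped phase (analytic outside-source
background fields, two independently noisy averages), cohort simulators with
known injected effects, and a multi-rater label simulator.

## Worked example

```python
import numpy as np
from ferromap import PipelineConfig, default_phantom_spec
from ferromap.pipeline import run_phantom_pipeline

spec = default_phantom_spec(n=64, snr=100)      # 3 regions + ventricle
res, gt = run_phantom_pipeline(PipelineConfig(), spec=spec)
for lid, (name, _, _) in gt.labels.lookup.items():
    true = gt.chi_true.data[gt.labels.data == lid][0]
    sel = (gt.labels.data == lid) & res.eroded_mask.data
    print(f"{name:12s} true {true:+.3f} ppm   recon {np.median(res.chi_referenced.data[sel]):+.4f} ppm")
```

prints (noise seed 20240601):

```
ventricle    true +0.000 ppm   recon -0.0002 ppm
L_deep_gray  true +0.100 ppm   recon +0.0975 ppm
R_lesion     true -0.050 ppm   recon -0.0454 ppm
L_cortex     true +0.050 ppm   recon +0.0493 ppm
```

i.e. region medians recovered within ~9 % through the complete chain
(unwrap → V-SHARP → detrend → MEDI → zero-reference).  The ventricle is the
reference region, so its value is zero by construction.

The same stages are scriptable from the shell:

```bash
ferromap phantom --size 64 --out scratch/phantom
ferromap recon --avg1-mag ... --avg1-phase ... --avg2-mag ... --avg2-phase ... \
               --out field.nii.gz --weights w.nii.gz
ferromap background --field field.nii.gz --mask mask.nii.gz --out local.nii.gz --out-mask eroded.nii.gz
ferromap invert --field local.nii.gz --weights w.nii.gz --mag mag.nii.gz --mask eroded.nii.gz --out chi.nii.gz
ferromap simulate-cohort --out cohort/   &&   ferromap stats --parcels cohort/parcel_values.tsv \
               --covariates cohort/covariates.tsv --out stats.tsv
```

The numbered drivers under `analysis/` reproduce the package's study-style
analyses (phantom simulation, reconstruction comparison, cohort statistics,
inter-rater agreement) and write their tables under `results/`.

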