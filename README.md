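# hotpvc

Model-free partial volume correction (PVC) for hot focal structures in PET,
with a digital lesion phantom simulator for end-to-end validation against
exactly known ground truth.

## The problem

The finite spatial resolution of PET (typically a point spread function of
6–8 mm FWHM) blurs every hot lesion into its surroundings. The displaced
signal — *spill-out* — makes the measured mean uptake (SUV_mean) of a lesion
systematically too low, by tens of percent for small lesions and still
noticeably for lesions of several hundred mL, because the partial volume
effect is a surface effect. Quantitative oncology (therapy response
assessment in particular) needs that loss put back.

`hotpvc` implements a model-free correction that recovers the spill-out
directly from the image, without deconvolution and without precise knowledge
of the scanner PSF. For an ROI with measured mean concentration C_mean and
volume V_ROI, the corrected mean is

    C_mean^corr = (A_ROI + A_sp) / V_ROI,        A_ROI = C_mean · V_ROI

where the spill-out activity is summed over a shell of voxels within one
FWHM of the ROI:

    A_sp = V_vox · Σ_{v ∈ sp} ( C(v) − B(v) )

Beyond one FWHM from the boundary the blurred signal of a hot object has
decayed to ~0.5 % of its amplitude, so the shell 0 < d ≤ FWHM captures the
displaced activity; the shell FWHM < d ≤ 2.5·FWHM serves as background.
The background B(v) is estimated **per voxel**: the mean of background-shell
voxels within 1.5·FWHM of v (LBPVC, local background PVC). Replacing B(v)
by the mean of the whole background shell gives the GBPVC variant, which is
noticeably worse for small lesions on non-uniform backgrounds. Spill-out
voxels with no background in reach (e.g. inside a necrotic core) fall back
to the global background mean.

The ROI boundary comes either from a supplied mask ("true boundary" mode)
or from the built-in delineator: an iterative background-adapted threshold
T = B + q·(C_max − B) with q = 0.39, where B is the mean of the matched
background shell around the current mask.

The package also generates anthropomorphic digital phantoms — irregular,
heterogeneous lesions (3–500 mL, contrasts ~3–13, intra-lesion CoV up to
0.22) on heterogeneous backgrounds, blurred with the PSF and degraded with
proportional Gaussian noise — so the whole chain can be validated against
exactly known truth. See `docs/methods.md` for the model details and design
choices.

## Worked example

```python
from hotpvc import (LesionSpec, NoiseModel, PsfModel, DelineationParams,
                    make_scene, delineate, run_lbpvc)

# a 30 mL heterogeneous lesion, contrast 8:1, 8 mm PSF, 5 % noise
scene = make_scene(
    [LesionSpec(volume_ml=30.0, contrast=8.0, heterogeneity_cov=0.18)],
    psf=PsfModel(8.0), noise=NoiseModel(5.0), spacing=4.0, seed=7,
)
truth = scene.true_stats[0]

roi = delineate(scene.measured_grid,
                DelineationParams(threshold_fraction=0.39, denoise_fwhm_mm=4.0),
                PsfModel(8.0))
result = run_lbpvc(scene.measured_grid, roi, psf=PsfModel(8.0))
```

Output of the full script (`seed=7`):

```
true volume : 30.02 mL
true mean   : 7.505
delineated volume : 30.72 mL
uncorrected mean  : 6.015
corrected mean    : 7.291
spill-out activity: 39.193
recovery (uncorrected): 0.802
deviation after LBPVC : -2.85 %
```

Reading: blurring depressed the measured mean to 80 % of truth (recovery
0.80); the delineator found the boundary within 2.3 % of the true volume;
summing the background-corrected spill-out shell recovered 39.2 activity
units, bringing the mean back to within −2.9 % of the true value.

## Command line

```bash
pvc simulate --config scene.yaml --seed 42 --out-dir scene/
pvc delineate --in scene/measured.nii.gz --q 0.39 --fwhm 8 --out mask.nii.gz
pvc correct  --in scene/measured.nii.gz --mask mask.nii.gz --fwhm 8 \
             --method lbpvc --out result.json
pvc evaluate --config exp.yaml --seed 42 --out records.csv
```

Volumes and masks are NIfTI (`.nii`/`.nii.gz`); all physical parameters are
in mm, mL and percent.

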