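# Methods

## The correction

A hot lesion imaged at resolution FWHM loses part of its activity across
its boundary (spill-out) and receives some background activity in exchange
(spill-in). For an ROI with measured in-mask mean C_mean and volume V_ROI
the corrected mean is

    C_mean^corr = (A_ROI + A_sp) / V_ROI,   A_ROI = C_mean · V_ROI,
    A_sp = V_vox · Σ_{v ∈ sp} ( C(v) − B(v) ),

where the sum runs over the *spill-out region* and B(v) is the background
concentration attributed to voxel v. The summand is the background-corrected
activity of v, so A_sp is automatically the *net* spill (spill-out minus
spill-in); it may be negative for faint lesions under noise and is then
propagated with a warning, never clamped — clamping would bias the
estimator.

### Shell geometry

All shell geometry is expressed in units of the assumed resolution:

* spill-out region: voxels with 3D Euclidean distance 0 < d ≤ FWHM to the
  ROI. For a homogeneous sphere the blurred signal one FWHM outside the
  boundary has decayed to ≈ 0.5 % of the true concentration (closed-form
  Gaussian-convolved-ball profile, `hotpvc.analytic`), which justifies
  truncating there.
* background region: FWHM < d ≤ 2.5·FWHM — close enough to be
  representative, large enough for statistical stability.
* per-voxel background search radius: equal to the width of the background
  region (nominally 1.5·FWHM).

Distances are measured voxel centre to nearest ROI-voxel centre with the
spacing-aware exact Euclidean distance transform; d = 0 inside the ROI.
Both shell bounds are snapped to the nearest whole multiple of the (mean)
voxel edge, halves rounding up; the search radius is the difference of the
snapped bounds. On 4 mm voxels this yields spill-out/background thicknesses
of 2/3 voxels at FWHM 8 mm, 1/2 at 4 mm and 3/5 at 12 mm — these three
cases are regression-tested to pin the rounding convention. Centre-to-centre
distance (rather than distance to a sub-voxel surface) is the natural
convention once bounds are rounded to whole voxels anyway.

Neighbouring ROIs and their own ≤ FWHM surroundings are excluded from the
background region. Shells truncated by the image border raise a warning and
use whatever shell voxels exist; an entirely empty background region is an
error because no correction is possible.

### Local vs global background

LBPVC computes B(v) for every spill-out voxel as the mean of
background-region voxels within the search radius of v (implemented exactly
as two correlations with a spherical footprint: masked sum divided by
count). GBPVC uses the background-region mean for every voxel. On a
homogeneous background the two coincide *exactly* (to double precision)
because every local average equals the global one; their difference grows
with background structure, and on a two-level background with the lesion
off-centre the local variant is demonstrably closer to truth. A spill-out
voxel with no background voxel in range — typically inside a central
necrosis — receives the global mean and is counted in
`PvcResult.n_fallback_voxels`.

Sums over shells use compensated (fsum) accumulation so results are
independent of voxel order.

### Sensitivity to the assumed resolution

The assumed FWHM enters only through the shell bounds. Underestimating it
(4 mm on 8 mm data) shrinks the spill-out shell below the true spill extent
and systematically undercorrects; overestimating it (12 mm) collects the
complete spill-out plus a little extra background fluctuation, giving a
slight overcorrection. Both behaviours are verified on the synthetic
lesion sets; the safe strategy with uncertain resolution is a pessimistic
(large) estimate.

## Delineation

The boundary estimator is an iterative background-adapted fractional
threshold:

    T = B + q · (C_max − B),    q = 0.39 (configurable)

with C_max the maximum inside the current mask and B the mean of the
matched background shell around the current mask (first iteration: the
image median, a robust background proxy before any shell exists). The mask
is the 26-connected component above T containing the seed; iteration stops
when the mask reproduces itself (a cycle returns the last mask with a
warning flag). q = 0.39 is a published convention for this family of
methods; on noiseless blurred spheres it recovers the volume to within a
few percent from 2·FWHM diameter upwards because the fractional threshold
tracks the radius where the blurred edge crosses ~40–50 % of the
background-corrected plateau.

Two implementation choices go beyond the bare threshold iteration:

* **Interior holes are filled.** A lesion includes its necrotic (cold)
  core; this is the same convention that motivates the necrosis fallback in
  the correction itself.
* **Optional thresholding pre-filter** (`denoise_fwhm_mm`, default off; the
  evaluation pipeline uses 4 mm). The threshold references the in-mask
  maximum, which noise inflates by several percent (the maximum over
  hundreds of voxels of multiplicative Gaussian noise), biasing the mask
  small. A narrow Gaussian pre-filter applied *only to the image used for
  thresholding* suppresses this; all reported statistics (C_mean, C_max,
  CoV) always come from the original image.

Lesions with equivalent-sphere diameter < 2·FWHM are flagged (not refused):
threshold delineation is unreliable there. The correction itself is
delineation-agnostic and accepts any externally supplied mask ("true
boundary" mode), which the validation uses to separate correction error
from delineation error.

## The phantom generator

No clinical images ship with this package, so validation runs on fully
synthetic anthropomorphic scenes with exactly known ground truth:

* **Geometry.** Sphere or blob (sphere with a smooth random radial
  perturbation, default amplitude 10 % of the radius); the nominal radius
  is bisected so the voxelized mask matches the requested volume to within
  half a voxel. Centres are jittered by up to half a voxel — real lesions
  are not lattice-aligned, and an off-lattice centre avoids
  symmetry-degenerate jumps in the voxel count.
* **Intensity.** The lesion replaces the background sharply (the sharp
  scene is the gold standard). Amplitude is scaled so the in-mask maximum
  over the mean background attains the requested contrast.
* **Heterogeneity.** Multiplicative smooth cold patches (correlation
  2·FWHM, so the structure survives blurring) whose amplitude ramps in with
  depth: zero within one FWHM of the boundary, full strength beyond two.
  The amplitude is bisected to the requested in-mask CoV. Rationale: in
  FDG-avid masses heterogeneity is dominated by cooler
  necrotic/hypometabolic interior structure under a comparatively uniform
  avid periphery, and a rim that is approximately an iso-intensity surface
  is precisely the regime in which threshold delineation of real lesions
  operates. Texture reaching the rim produces lesions that no fractional
  threshold can delineate to within 10 % — harder than anything the
  method's validation domain contains.
* **Attainability.** The requested CoV needs interior volume. Lesions with
  little volume deeper than one FWHM saturate below the request; the
  generator then delivers the closest attainable texture, and all scene
  statistics report *attained* values. For the same reason the default
  experiment draws CoV targets uniformly with a size-dependent upper bound
  (lower end of 0.13–0.22 near 4 mL, full range from ~30 mL upward).
* **Background.** A smooth multiplicative random field (default 5 %
  relative sd, 40 mm correlation) around a constant mean, with an optional
  left/right step for local-vs-global background experiments.
* **Measurement.** `measured = noise(smooth(sharp))`: isotropic Gaussian
  PSF in mm (FWHM/2.3548 → σ; reflect-padding at borders, irrelevant in
  practice because lesions keep ≥ 2.5·FWHM clearance), then independent
  per-voxel Gaussian noise with sd = (noise FWHM %)/2.3548 of the local
  intensity, applied to the whole image after smoothing. Negative values
  are kept. Noise FWHM presets 3.5/5/7.1/10 % correspond to 2×/1×/½×/¼×
  equivalent scan time. Every random draw derives from one scene seed;
  scenes are bitwise reproducible.

`sharpen_edges` implements the converse transform used to build phantoms
*from measured images*: every spill-out voxel is replaced by its local
background B(v) (the identical operator the correction uses) and the
removed difference is returned, split equally, over the ROI voxels within
the search radius of that voxel — conserving the total activity of
ROI ∪ spill-out exactly. Contributions from several spill-out voxels to the
same object voxel accumulate. A spill-out voxel with no ROI voxel in range
sends its difference to the nearest ROI voxel and is counted in a warning.

`reduce_contrast` divides the sharp values inside one lesion by a constant
factor and rebuilds the measured scene with the same noise realisation, for
low-contrast experiments.

What the phantoms do *not* emulate: reconstruction physics (the PSF is a
shift-invariant Gaussian, noise is uncorrelated between voxels, whereas
OSEM noise is spatially correlated and object-dependent), scatter,
attenuation artefacts, respiratory motion, and anatomically structured
backgrounds. Passing tests therefore establish the correction's behaviour
under its stated model — resolution loss by Gaussian blurring with
proportional noise — not its performance on any particular scanner.

## The validation experiments

The default experiment (`ExperimentConfig`) evaluates 20 single-lesion
scenes with volumes log-spaced over 3–500 mL, contrasts uniform in 4–13,
size-capped CoV targets in 0.13–0.22, 4 mm voxels, true PSF 8 mm and noise
FWHM 5 %, each lesion in both boundary modes (true mask / automatic
delineation) for the methods none/GBPVC/LBPVC — a desk-scale rendition of
a 37-lesion clinical-phantom study design; the whole batch runs in a few
seconds. Deviations are reported in signed percent,
100·(corrected − true)/true; the recovery coefficient is reported both raw
(mean/true-mean) and background-subtracted, since the literature uses both
conventions. Variant runs raise the noise to 7.1 %/10 % or replace the
assumed resolution by 4 or 12 mm.

Typical behaviour at these problem sizes: uncorrected recoveries of
0.6–0.95 depending on size; with the true boundary LBPVC recovers means to
within ~3 % for every lesion; with automatic delineation volumes stay
within ±10 % and corrected means within ±10 % (within ±15 % at doubled and
quadrupled-equivalent noise and for an assumed resolution of 12 mm, while
4 mm produces a systematic negative bias). These envelopes — not any
specific per-lesion numbers — are what `tests/test_acceptance.py` asserts
and `scripts/acceptance.py` recomputes.

## Numerical conventions

* FWHM → σ conversion: 1/(2·√(2·ln 2)); all geometry in mm, supporting
  anisotropic voxels.
* Voxel volume: ∏ spacing / 1000 (mL).
* CoV: population standard deviation over mean of in-mask voxels.
* Shell membership: centre distance ≤ bound + 1e−9 (ties include).
* Seed handling: every experiment seed spawns independent child streams
  (numpy `SeedSequence`) per scene, lesion, background and noise draw; all
  derived seeds stay below 2³¹.

## Known limitations

* Threshold delineation fails below 2·FWHM equivalent diameter and for
  heavily heterogeneous or very low contrast (< ~2.5) lesions; the
  correction inherits those limits because it needs a boundary.
* The correction recovers C_mean, not C_max, and does not attempt
  deconvolution or CT/MRI-guided correction.
* The generator's heterogeneity model is smooth and interior-dominated;
  rim-dominated heterogeneity (e.g. hypermetabolic rims around photopenic
  centres at matched overall CoV) is outside its repertoire and would
  require a delineation method beyond fractional thresholding.
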