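# Methods

This note documents the models, numerical choices and open design
decisions behind `temcao`, and what the phantom-based tests do and do
not establish about real data.

## Signal models and relaxometry

Both quantitative fits assume mono-exponential decay:
`S(TE) = S₀·exp(−TE/T2)` for the multi-echo series and
`S(b) = S₀·exp(−b·ADC)` for the diffusion series. The default estimator
is ordinary least squares on the log-transformed signal — closed-form,
deterministic, and the standard choice for a 3-point ADC protocol; a
Levenberg–Marquardt refinement on the raw signal is available behind
`nonlinear=True` and agrees with the log-linear fit to well under 1% on
noise-free data. The fit runs on any series with ≥2 samples, which
covers both the 10-echo volume-coil protocol (10–100 ms) and the 3-echo
surface-coil variant (15/45/75 ms).

Voxels are flagged invalid — excluded from the validity mask and set to
zero in every map — when any sample is non-positive or the fitted decay
rate is non-positive (constant or rising signal). No noise-floor
(Rician-bias) correction is applied; at the 2% noise level modeled, the
resulting bias on T2 is well under the 5% tolerance the tests enforce,
but users fitting low-SNR data should be aware of it.

Units: T2 in ms, R2 = 1/T2 in 1/ms, ADC in mm²/s. All downstream
thresholds operate on harmonized (unitless) maps, so these choices are
internal.

## Preprocessing and harmonization

The stage order is fixed: denoise → resample → fit maps → harmonize.

* Denoising: adaptive non-local means (3³ patches, 7³ search window,
  strength tied to a per-volume noise estimate). Only the method is
  protocol-specified; the window sizes are conventional defaults.
* Resampling: tricubic (spline order 3) interpolation to 0.15 mm
  isotropic, preserving the world extent to within one voxel. A memory
  guard rejects pathological anisotropy.
* Brain extraction: Otsu threshold, morphological closing (ball radius
  2), hole fill, largest connected component. This deliberately replaces
  the learned extractor used in the original deployment, whose weights
  are not public; everything scientific happens downstream of the mask,
  and a user-supplied mask is passed through untouched.
* Harmonization: each map is divided by the mode of its smoothed
  in-brain histogram (256 bins over the in-mask range, Gaussian-smoothed
  with σ = 2 bins; the mode is the argmax bin center). The mode is
  robust to the skew a focal lesion adds, which is why it is preferred
  over the mean or median. Harmonization is applied to the fitted R2 and
  ADC maps — the quantities that are thresholded — rather than to raw
  scans; the alternative reading (harmonizing each raw scan) would
  change only where the division happens, since the lesion thresholds
  are calibrated on mode-one maps.

## Lesion and CSF segmentation

At 48 h after occlusion, edema raises T2 (so harmonized R2 falls below
the tissue mode of 1) and cytotoxic injury lowers ADC; CSF has much
longer T2 still, and free diffusion. Two oriented channels encode this:

* `r2_channel = 1 / (1 + exp(slope·(R2_h − center)))` — a falling
  sigmoid, high wherever T2 is elevated (lesion **and** CSF);
* `adc_channel = 1 / ADC_h` — above one where diffusion is restricted
  (lesion), far below one in CSF.

Initial masks are conjunctions of fixed thresholds on these channels:
lesion = `r2_channel > 0.8 ∧ adc_channel > 1.5`; CSF =
`r2_channel > 0.75 ∧ adc_channel < 1.25`. With the default tissue
contrasts (harmonized lesion ≈ (R2 0.63, ADC 0.57), CSF ≈ (0.33, 3.0),
normal = (1, 1)) these four constants separate the three classes
exactly. The sigmoid centers (0.85 for R2, 0.80 for ADC, slope 8) sit
below the tissue mode so that normal tissue scores ≈0.2 — safely under
the weak hysteresis threshold; centering the sigmoids at the mode itself
would pin normal tissue at exactly 0.5, inside the hysteresis band, and
let any strong seed flood the whole brain.

Refinement smooths the [0,1] lesion score (Gaussian, σ = 1 voxel) and
applies hysteresis thresholding: voxels above the weak threshold (0.45)
are kept only if 26-connected to a voxel above the strong threshold
(0.55) that also lies in the initial mask. With smoothing disabled this
is exactly a flood fill from strong seeds, and the test suite verifies
that equivalence against a brute-force BFS oracle. CSF uses the same
machinery with an ADC-rising score channel; voxels claimed by both masks
go to the lesion, with the contested count logged.

Morphometry: the lesion volume fraction divides the lesion volume by the
ipsilateral (right) hemisphere volume, both by voxel counting. The
hemisphere split uses the **atlas** midline, not the shifted estimate,
so the denominator is stable under mass effect; the hemisphere includes
ventricular CSF voxels (they are brain-mask voxels), and excluding them
is left to the caller via the masks. The midline shift is the distance
between the atlas sagittal midplane and the sagittal plane through the
centroid of CSF voxels inside the ventricle ROI; the index divides by
the brain width (maximal left-right extent of the brain mask).

## Vessel extraction and occlusion classification

TOF volumes are contrast-stretched between the 1st and 99.9th intensity
percentiles (the upper tail must not saturate the vessels, which occupy
well under 1% of the field of view), then filtered with multi-scale
Frangi vesselness (scales 1–3 voxels, α = β = 0.5, scikit-image
implementation) normalized to [0, 1]; responses below 0.1 of the
maximum are zeroed, and the binary mask thresholds at 0.02 of the
maximum with components under 10 voxels removed. Marching cubes at
iso-level 0.5 of the zero-padded mask yields a closed triangle surface
in mm, exported as ASCII PLY; surface area and divergence-theorem volume
are available for sanity checks.

Segment presence (ACA, MCA, PCA, distal ICA) is a deterministic
continuity test: two anatomical seed points per segment must be joined
by a 26-connected path inside the vessel mask restricted to that
segment's territory ROI. The occlusion class follows a fixed decision
table: both MCA and distal ICA absent → `T_occlusion`; MCA and ACA
absent (ICA present) → `MCA_ACA`; only MCA absent → `MCA`; distal ICA
absent with MCA present → `distal_ICA`; all present → `none`. Presence
maps outside these patterns (e.g. an isolated PCA dropout) return
`other`, and any unassessed segment returns `unknown` — never a silent
default. Where a human rater would combine mesh inspection with the
enhanced TOF images, this classifier is fully automatic; the mesh is
kept for visualization.

## Behavioral scores

The corner index is `abs((L − R)/(L + R))` over up to 10 trials; with no
completed turns it is undefined and propagated as missing, never 0. The
neurodeficit score defaults to one point per observed deficit category
(asymmetric forelimb/torso turning, circling, inability to bear weight,
absence of movement; range 0–4), since follow-up scores evolve gradually
rather than binarily; the strict any-deficit reading (0/1) is available
as `mode="binary"`. The battery composite is the plain sum of nine 0–3
items; the timed beam-walk and grid-climb tests enter as pre-scored
items — mapping raw timings to 0–3 happens at the testing site and is
out of scope.

## Cohort accounting

The event ledger is a long-format CSV (subject_id, site, sex, role,
event, day, value); attributes such as TNK dose and timing are rows of
their own. Populations are defined by events: ITT = enrolled − donors;
mITT requires a completed thrombus injection; FT requires both
thrombolysis and study-drug events; Full Analysis drops FT subjects with
a death event. Compliance defaults: dose 1.5 mg/kg (±0.01), interval
120 ± 16 min (the tightest symmetric window covering the observed
118–136 min range; no window is protocol-printed), thrombus length
4.5–6.0 cm, donor-sex match. Missing attributes are counted
unassessable — excluded from both numerator and denominator and reported
separately, never passed.

Survival uses the hand-rolled Kaplan–Meier product-limit estimator
(pooling tied deaths), with subjects lost after treatment treated as
deaths at their recorded day — the study's curves show survival only, so
no competing-risk model is fitted. Survivors are censored at day 30. The
estimator is cross-checked against `lifelines` in the tests. The
mortality table counts deaths by days 3/7/30 per site over that site's
operated (mITT) population, with percentages rounded to two decimals.

## The phantom: what it does and does not emulate

The phantom reproduces the study's acquisition geometry (128×128×30 at
150 µm, 10 echoes 10–100 ms, b = 0/500/1000 s/mm²) around analytic
primitives — an ellipsoidal brain (12 mm wide), paired lateral plus
third ventricles, a spherical right-hemisphere lesion, and a
four-segment vessel fork — voxelized by center-of-voxel inclusion, so
every truth mask is exact on the grid. Default tissue parameters
(normal T2 50 ms / ADC 0.7·10⁻³ mm²/s; lesion 80 ms / 0.4·10⁻³; CSF
150 ms / 2.1·10⁻³) are representative values for rat brain at high
field with 48-h ischemic edema. Noise is Rician — the magnitude of
signal plus complex Gaussian — with σ given relative to tissue S₀; the
2% default matches good small-animal SNR. Lesion size is solved by
bisection on the voxelized fraction, so a requested lesion volume
fraction is hit to well under 0.01; an unreachable target is reported
with the achieved fraction rather than failing. The midline-shift
parameter displaces the whole ventricle system laterally.

Deliberately not modeled: realistic rat neuroanatomy, B1/bias fields,
partial-volume gradients at tissue borders, motion or ghosting
artifacts, susceptibility effects, pulsatile flow. Consequently the
recovery tests demonstrate the correctness and internal consistency of
the algorithms — threshold calibration, hysteresis behavior, geometry
and arithmetic — not segmentation accuracy on real scans, where contrast
overlaps between classes and anatomy is far less convenient.

## Problem sizes and determinism

All randomness flows through explicit integer seeds
(`numpy.random.default_rng`); identical spec + seed gives bit-identical
phantoms. The test suite runs the full-geometry (128×128×30) pipeline
for the lesion-fraction grid {0, 0.05, 0.13, 0.30} and the midline-shift
recovery, and uses 64×64×20 phantoms where the full field of view adds
nothing (relaxometry statistics, cohort simulations with n = 1000).
`scripts/acceptance.py` re-derives every reported quantity at run time
from these same generators.
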