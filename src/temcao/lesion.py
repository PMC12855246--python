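"""Lesion / CSF segmentation, lesion volume fraction and midline shift.

Works on harmonized maps (histogram mode scaled to one, see
:mod:`temcao.preprocess`), so all thresholds below are unitless.

Tissue contrast model.  At 48 h post-occlusion, ischemic edema raises T2
— lowering R2 = 1/T2 below the normal-tissue mode — and cytotoxic injury
lowers ADC.  CSF has by far the longest T2 (the lowest R2) and free
diffusion (the highest ADC).  Two oriented "likeness" channels encode
this:

* ``r2_channel``  — a falling sigmoid of harmonized R2; high wherever T2
  is elevated (both lesion and CSF score high, normal tissue low);
* ``adc_channel`` — the reciprocal of harmonized ADC; above one wherever
  diffusion is restricted (lesion), below one where it is free (CSF).

The initial lesion mask is the conjunction ``r2_channel > 0.8`` and
``adc_channel > 1.5``; CSF is ``r2_channel > 0.75`` with
``adc_channel < 1.25``.  On these channels the four printed constants
cleanly separate normal tissue, lesion and CSF.  The initial mask is
then refined by Gaussian smoothing of a [0, 1] lesion score and
hysteresis thresholding (strong = 0.55, weak = 0.45, 26-connectivity):
weak voxels survive only if connected to a strong seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .volume import QuantVolume

__all__ = [
    "LesionConfig",
    "SegmentationResult",
    "MidlineResult",
    "lesion_score",
    "initial_lesion_mask",
    "refine_hysteresis",
    "segment_csf",
    "split_hemispheres",
    "lesion_volume_fraction",
    "midline_shift",
]

log = logging.getLogger(__name__)

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class LesionConfig:
    """Thresholds and transform parameters for lesion/CSF segmentation.

    The initial and CSF thresholds are the protocol's printed constants;
    the sigmoid centers/slopes and the smoothing width are this
    implementation's calibration (the protocol does not print them).
    The sigmoid centers sit below the tissue mode (1.0) so that normal
    tissue scores well under the weak hysteresis threshold.
    """

    r2_sigmoid_center: float = 0.85
    r2_sigmoid_slope: float = 8.0
    adc_sigmoid_center: float = 0.80
    adc_sigmoid_slope: float = 8.0
    csf_adc_sigmoid_center: float = 1.60
    csf_adc_sigmoid_slope: float = 8.0
    r2_initial_threshold: float = 0.8
    adc_initial_threshold: float = 1.5
    hysteresis_strong: float = 0.55
    hysteresis_weak: float = 0.45
    csf_r2_threshold: float = 0.75
    csf_adc_threshold: float = 1.25
    smoothing_sigma_voxels: float = 1.0

    def validate(self) -> None:
        if not self.hysteresis_weak < self.hysteresis_strong:
            raise ValueError("hysteresis weak threshold must be below strong")
        for name in ("r2_initial_threshold", "adc_initial_threshold",
                     "csf_r2_threshold", "csf_adc_threshold"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if self.smoothing_sigma_voxels < 0:
            raise ValueError("smoothing sigma must be non-negative")


@dataclass
class SegmentationResult:
    lesion_mask: np.ndarray
    csf_mask: np.ndarray
    ipsilateral_mask: np.ndarray
    contralateral_mask: np.ndarray
    lesion_volume_mm3: float
    hemisphere_volume_mm3: float
    lesion_volume_fraction: float


@dataclass
class MidlineResult:
    ventricle_csf_centroid_mm: tuple[float, float, float]
    estimated_midline_x_mm: float
    absolute_shift_mm: float
    brain_width_mm: float
    midline_shift_index: float


def _falling_sigmoid(x: np.ndarray, center: float, slope: float) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(np.clip(slope * (x - center), -60, 60)))


def _rising_sigmoid(x: np.ndarray, center: float, slope: float) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(np.clip(-slope * (x - center), -60, 60)))


def _check_harmonized(data: np.ndarray, mask: np.ndarray, what: str) -> None:
    vals = data[mask & (data > 0)]
    if vals.size and not 0.3 < float(np.median(vals)) < 3.0:
        log.warning("%s does not look harmonized (in-mask median %.3g, expected ~1)",
                    what, float(np.median(vals)))


def _reciprocal(data: np.ndarray) -> np.ndarray:
    out = np.zeros_like(data, dtype=np.float64)
    pos = data > 0
    out[pos] = 1.0 / data[pos]
    return out


def lesion_score(r2_h: QuantVolume, adc_h: QuantVolume,
                 config: LesionConfig | None = None,
                 brain_mask: np.ndarray | None = None) -> np.ndarray:
    """Per-voxel lesion-likeness in [0, 1].

    The minimum of two falling sigmoids — one on harmonized R2 (high T2
    scores high) and one on harmonized ADC (restricted diffusion scores
    high) — so a voxel must look lesion-like on both maps.  Normal tissue
    at the mode scores well below the initial threshold; CSF is killed by
    its high ADC.
    """
    config = config or LesionConfig()
    config.validate()
    r2 = np.asarray(r2_h.data, dtype=np.float64)
    adc = np.asarray(adc_h.data, dtype=np.float64)
    if brain_mask is None:
        brain_mask = np.ones(r2.shape, dtype=bool)
    _check_harmonized(r2, brain_mask, "R2 map")
    _check_harmonized(adc, brain_mask, "ADC map")
    s_r2 = _falling_sigmoid(r2, config.r2_sigmoid_center, config.r2_sigmoid_slope)
    s_adc = _falling_sigmoid(adc, config.adc_sigmoid_center, config.adc_sigmoid_slope)
    score = np.minimum(s_r2, s_adc)
    score[~brain_mask] = 0.0
    return score


def initial_lesion_mask(r2_h: QuantVolume, adc_h: QuantVolume,
                        config: LesionConfig | None = None,
                        brain_mask: np.ndarray | None = None) -> np.ndarray:
    """Conjunction of the two channel thresholds: candidate lesion voxels."""
    config = config or LesionConfig()
    config.validate()
    r2 = np.asarray(r2_h.data, dtype=np.float64)
    adc = np.asarray(adc_h.data, dtype=np.float64)
    r2_chan = _falling_sigmoid(r2, config.r2_sigmoid_center, config.r2_sigmoid_slope)
    adc_chan = _reciprocal(adc)
    mask = (r2_chan > config.r2_initial_threshold) & (adc_chan > config.adc_initial_threshold)
    if brain_mask is not None:
        mask &= np.asarray(brain_mask, dtype=bool)
    return mask


def refine_hysteresis(score: np.ndarray, initial_mask: np.ndarray | None,
                      config: LesionConfig | None = None) -> np.ndarray:
    """Smooth the score and keep weak-threshold voxels 26-connected to a
    strong seed.

    Strong seeds are additionally restricted to the initial mask when one
    is given.  With ``smoothing_sigma_voxels == 0`` this is exactly a
    flood fill from strong voxels through the weak set.  An empty strong
    set yields an empty mask.
    """
    config = config or LesionConfig()
    config.validate()
    score = np.asarray(score, dtype=np.float64)
    if config.smoothing_sigma_voxels > 0:
        score = ndi.gaussian_filter(score, config.smoothing_sigma_voxels)
    strong = score >= config.hysteresis_strong
    if initial_mask is not None:
        strong &= np.asarray(initial_mask, dtype=bool)
    if not strong.any():
        return np.zeros(score.shape, dtype=bool)
    weak = score >= config.hysteresis_weak
    structure = _STRUCT26 if score.ndim == 3 else np.ones((3,) * score.ndim, dtype=bool)
    labels, _ = ndi.label(weak, structure=structure)
    keep = np.unique(labels[strong])
    keep = keep[keep > 0]
    return np.isin(labels, keep)


def segment_csf(r2_h: QuantVolume, adc_h: QuantVolume,
                config: LesionConfig | None = None,
                brain_mask: np.ndarray | None = None,
                lesion_mask: np.ndarray | None = None) -> np.ndarray:
    """CSF mask: long-T2, free-diffusion voxels, hysteresis-refined.

    Voxels contested with the lesion mask go to the lesion (count logged).
    """
    config = config or LesionConfig()
    config.validate()
    r2 = np.asarray(r2_h.data, dtype=np.float64)
    adc = np.asarray(adc_h.data, dtype=np.float64)
    r2_chan = _falling_sigmoid(r2, config.r2_sigmoid_center, config.r2_sigmoid_slope)
    adc_chan = _reciprocal(adc)
    initial = (r2_chan > config.csf_r2_threshold) & \
              (adc_chan > 0) & (adc_chan < config.csf_adc_threshold)
    s_adc_high = _rising_sigmoid(adc, config.csf_adc_sigmoid_center,
                                 config.csf_adc_sigmoid_slope)
    score = np.minimum(r2_chan, s_adc_high)
    if brain_mask is not None:
        brain_mask = np.asarray(brain_mask, dtype=bool)
        initial &= brain_mask
        score = np.where(brain_mask, score, 0.0)
    csf = refine_hysteresis(score, initial, config)
    if lesion_mask is not None:
        contested = int((csf & lesion_mask).sum())
        if contested:
            log.info("segment_csf: %d voxels contested with lesion; lesion wins", contested)
        csf &= ~np.asarray(lesion_mask, dtype=bool)
    return csf


def split_hemispheres(brain_mask: np.ndarray, spacing, atlas_midline_x_mm: float):
    """Split the brain at the atlas sagittal mid-plane.

    The atlas plane (not the shifted ventricle estimate) defines the
    hemispheres so the volume-fraction denominator is stable under mass
    effect.  Returns (ipsilateral/right, contralateral/left).
    """
    brain_mask = np.asarray(brain_mask, dtype=bool)
    x_mm = np.arange(brain_mask.shape[0]) * spacing[0]
    right = (x_mm > atlas_midline_x_mm)[:, None, None]
    return brain_mask & right, brain_mask & ~right


def lesion_volume_fraction(lesion_mask: np.ndarray, ipsilateral_mask: np.ndarray,
                           contralateral_mask: np.ndarray,
                           spacing) -> SegmentationResult:
    """Lesion volume over ipsilateral hemisphere volume (voxel counting)."""
    lesion_mask = np.asarray(lesion_mask, dtype=bool)
    ipsi = np.asarray(ipsilateral_mask, dtype=bool)
    voxel = float(np.prod(spacing))
    hemi_vox = int(ipsi.sum())
    if hemi_vox == 0:
        raise ValueError("empty ipsilateral hemisphere mask")
    lesion_vox = int((lesion_mask & ipsi).sum())
    frac = lesion_vox / hemi_vox
    return SegmentationResult(
        lesion_mask=lesion_mask,
        csf_mask=np.zeros_like(lesion_mask),
        ipsilateral_mask=ipsi,
        contralateral_mask=np.asarray(contralateral_mask, dtype=bool),
        lesion_volume_mm3=int(lesion_mask.sum()) * voxel,
        hemisphere_volume_mm3=hemi_vox * voxel,
        lesion_volume_fraction=frac,
    )


def midline_shift(csf_mask: np.ndarray, ventricle_roi: np.ndarray,
                  brain_mask: np.ndarray, spacing,
                  atlas_midline_x_mm: float,
                  subject_id: str | None = None) -> MidlineResult:
    """Midline shift from the ventricular CSF centroid.

    The centroid of CSF voxels inside the atlas ventricle ROI estimates
    the anatomical midpoint; the estimated midline is the sagittal plane
    through it, and the absolute shift is its distance to the atlas
    midline.  The index divides by the brain width (maximal left-right
    extent of the brain mask).
    """
    csf_mask = np.asarray(csf_mask, dtype=bool)
    roi = np.asarray(ventricle_roi, dtype=bool)
    brain_mask = np.asarray(brain_mask, dtype=bool)
    sel = csf_mask & roi
    if not sel.any():
        who = f" for subject {subject_id}" if subject_id else ""
        raise ValueError(f"no CSF voxels inside the ventricle ROI{who}")
    idx = np.argwhere(sel).astype(np.float64)
    centroid = tuple(float(c) for c in idx.mean(axis=0) * np.asarray(spacing))
    xs = np.nonzero(brain_mask.any(axis=(1, 2)))[0]
    if xs.size == 0:
        raise ValueError("empty brain mask")
    width = float((xs.max() - xs.min() + 1) * spacing[0])
    shift = abs(centroid[0] - atlas_midline_x_mm)
    return MidlineResult(
        ventricle_csf_centroid_mm=centroid,
        estimated_midline_x_mm=centroid[0],
        absolute_shift_mm=shift,
        brain_width_mm=width,
        midline_shift_index=shift / width,
    )
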