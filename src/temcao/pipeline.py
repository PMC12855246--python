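"""End-to-end per-subject analysis: raw series to quantitative metrics.

Stage order is fixed — denoise, resample to isotropic, parameter-map
fitting, brain extraction, harmonization, lesion/CSF segmentation,
volume fraction and midline shift, then (optionally) the angiography
chain.  Every stage logs its parameters, giving a provenance record of
the run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import angio as angio_mod
from . import lesion as lesion_mod
from . import preprocess as prep
from .relaxometry import fit_param_maps
from .volume import DWISeries, EchoSeries, QuantVolume

__all__ = ["PipelineConfig", "SubjectAtlas", "SubjectResult", "analyze_subject"]

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    preprocess: prep.PreprocessConfig = field(default_factory=prep.PreprocessConfig)
    lesion: lesion_mod.LesionConfig = field(default_factory=lesion_mod.LesionConfig)
    angio: angio_mod.AngioConfig = field(default_factory=angio_mod.AngioConfig)
    denoise: bool = True
    resample: bool = True


@dataclass
class SubjectAtlas:
    """Anatomical priors a site supplies per subject (the phantom carries
    its own): the sagittal midline, a ventricle ROI near the corpus
    callosum, and per-segment vascular territories with seed pairs."""

    atlas_midline_x_mm: float
    ventricle_roi: np.ndarray
    territory_rois: dict[str, np.ndarray] | None = None
    segment_seeds: dict[str, tuple] | None = None
    brain_mask: np.ndarray | None = None


@dataclass
class SubjectResult:
    maps_t2: QuantVolume
    maps_adc: QuantVolume
    r2_harmonized: QuantVolume
    adc_harmonized: QuantVolume
    brain_mask: np.ndarray
    segmentation: lesion_mod.SegmentationResult
    midline: lesion_mod.MidlineResult | None
    angio: angio_mod.AngioResult | None
    metrics: dict


def _prep_series(series, config: PipelineConfig):
    cls = type(series)
    vols = []
    for i in range(series.signal.shape[3]):
        v = series.volume(i)
        if config.denoise:
            v = prep.denoise(v, config.preprocess)
        if config.resample:
            v = prep.resample_isotropic(v, config.preprocess.target_spacing_mm)
        vols.append(v)
    data = np.stack([v.data for v in vols], axis=3)
    key = series.te_list_ms if isinstance(series, EchoSeries) else series.b_values
    return cls(data, key, vols[0].spacing)


def analyze_subject(echo: EchoSeries, dwi: DWISeries, atlas: SubjectAtlas,
                    tof: QuantVolume | None = None,
                    config: PipelineConfig | None = None,
                    subject_id: str | None = None) -> SubjectResult:
    """Run the full quantitative pipeline for one subject.

    The ventricle ROI and any user brain mask must be on the processed
    (isotropic) grid.  Midline shift is skipped (with a log message)
    when no CSF falls inside the ventricle ROI.
    """
    config = config or PipelineConfig()

    echo_p = _prep_series(echo, config)
    dwi_p = _prep_series(dwi, config)

    maps = fit_param_maps(echo_p, dwi_p)
    brain = prep.extract_brain(echo_p.volume(0), mask=atlas.brain_mask)
    fit_brain = brain & maps.fit_validity_mask

    r2_h, r2_mode = prep.harmonize_mode(maps.r2_per_ms, fit_brain, config.preprocess)
    adc_h, adc_mode = prep.harmonize_mode(maps.adc_mm2_s, fit_brain, config.preprocess)

    score = lesion_mod.lesion_score(r2_h, adc_h, config.lesion, fit_brain)
    initial = lesion_mod.initial_lesion_mask(r2_h, adc_h, config.lesion, fit_brain)
    lesion_mask = lesion_mod.refine_hysteresis(score, initial, config.lesion) & fit_brain
    csf_mask = lesion_mod.segment_csf(r2_h, adc_h, config.lesion, fit_brain, lesion_mask)

    spacing = echo_p.spacing
    ipsi, contra = lesion_mod.split_hemispheres(brain, spacing, atlas.atlas_midline_x_mm)
    seg = lesion_mod.lesion_volume_fraction(lesion_mask, ipsi, contra, spacing)
    seg.csf_mask = csf_mask

    midline = None
    try:
        midline = lesion_mod.midline_shift(csf_mask, atlas.ventricle_roi, brain,
                                           spacing, atlas.atlas_midline_x_mm,
                                           subject_id=subject_id)
    except ValueError as exc:
        log.warning("midline shift unavailable: %s", exc)

    angio_result = None
    if tof is not None and atlas.territory_rois and atlas.segment_seeds:
        angio_result = angio_mod.run_angio(tof, atlas.territory_rois,
                                           atlas.segment_seeds, config.angio)

    metrics = {
        "subject_id": subject_id,
        "r2_mode": r2_mode,
        "adc_mode": adc_mode,
        "lesion_volume_mm3": seg.lesion_volume_mm3,
        "hemisphere_volume_mm3": seg.hemisphere_volume_mm3,
        "lesion_volume_fraction": seg.lesion_volume_fraction,
        "midline_shift_mm": midline.absolute_shift_mm if midline else None,
        "midline_shift_index": midline.midline_shift_index if midline else None,
        "occlusion_class": angio_result.occlusion_class if angio_result else None,
    }
    return SubjectResult(maps.t2_ms, maps.adc_mm2_s, r2_h, adc_h, brain,
                         seg, midline, angio_result, metrics)
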