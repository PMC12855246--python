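"""Synthetic multi-contrast rodent-brain phantom with exact ground truth.

The phantom emulates the study's imaging geometry — a 128 x 128 x 30
matrix at 150 um isotropic spacing, 10 echoes from 10 to 100 ms, and
b-values of 0, 500 and 1000 s/mm² — around an analytic head model:

* an ellipsoidal brain split by the sagittal atlas mid-plane into left
  (contralateral) and right (ipsilateral) hemispheres;
* paired lateral ventricles plus a third ventricle, CSF-filled, which
  can be displaced laterally to emulate mass-effect midline shift;
* a spherical right-hemisphere lesion with elevated T2 and reduced ADC,
  sized by bisection to hit a requested lesion volume fraction;
* a branching vessel tree (distal ICA, MCA, ACA, PCA tubes) bright on
  TOF, with any subset of segments occluded (dark).

Geometry is voxelized by center-of-voxel inclusion against the analytic
primitives, so every truth mask is exact on the grid.  Signals follow
the mono-exponential forward models S(TE) = S0*exp(-TE/T2) and
S(b) = S0*exp(-b*ADC); Rician noise is applied as the magnitude of the
signal plus complex Gaussian noise with scale ``noise_sigma`` relative
to the normal-tissue S0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .cohort import LEDGER_COLUMNS, CohortLedger
from .volume import DWISeries, EchoSeries, QuantVolume

__all__ = [
    "SEGMENT_LABELS",
    "TissueParams",
    "TubeSegment",
    "PhantomSpec",
    "PhantomTruth",
    "generate_phantom",
    "EventRates",
    "generate_cohort",
]

log = logging.getLogger(__name__)

SEGMENT_LABELS = ("ICA", "MCA", "ACA", "PCA")

# voxel class codes
BACKGROUND, NORMAL, LESION, CSF = 0, 1, 2, 3


@dataclass(frozen=True)
class TissueParams:
    """Relaxation/diffusion/TOF parameters of one tissue class."""

    t2_ms: float
    adc_mm2_s: float
    s0: float
    tof: float


@dataclass(frozen=True)
class TubeSegment:
    """A straight vessel tube in world mm, relative to the brain center."""

    start_mm: tuple[float, float, float]
    end_mm: tuple[float, float, float]
    radius_mm: float
    label: str


def _default_vessel_tree() -> tuple[TubeSegment, ...]:
    # a circle-of-Willis-like fork on the right (ipsilateral) side:
    # the distal ICA ascends anteriorly and splits into MCA (lateral),
    # ACA (medial-anterior) and PCA (posterior) branches.
    r = 0.3
    junction = (1.5, -1.0, 0.0)
    return (
        TubeSegment((1.5, -5.5, -0.8), junction, r, "ICA"),
        TubeSegment(junction, (5.2, 2.5, 0.0), r, "MCA"),
        TubeSegment(junction, (0.3, 4.5, 0.0), r, "ACA"),
        TubeSegment(junction, (4.5, -4.0, 0.0), r, "PCA"),
    )


def _default_tissue_params() -> dict[str, TissueParams]:
    # Normal tissue anchors the harmonization mode; the lesion models
    # 48-h ischemic edema (T2 up, ADC down); CSF has long T2 and free
    # diffusion.  Background generates no signal.
    return {
        "normal": TissueParams(t2_ms=50.0, adc_mm2_s=0.70e-3, s0=100.0, tof=1.0),
        "lesion": TissueParams(t2_ms=80.0, adc_mm2_s=0.40e-3, s0=100.0, tof=1.0),
        "csf": TissueParams(t2_ms=150.0, adc_mm2_s=2.10e-3, s0=100.0, tof=0.8),
        "background": TissueParams(t2_ms=1.0, adc_mm2_s=1e-3, s0=0.0, tof=0.0),
    }


@dataclass
class PhantomSpec:
    """Full phantom description; defaults reproduce the study's protocol."""

    matrix_shape: tuple[int, int, int] = (128, 128, 30)
    voxel_size_mm: float = 0.15
    te_list_ms: tuple[float, ...] = tuple(float(t) for t in range(10, 101, 10))
    b_values: tuple[float, ...] = (0.0, 500.0, 1000.0)
    lesion_fraction_target: float = 0.13
    lesion_center_mm: tuple[float, float, float] = (3.2, 0.0, 0.0)  # rel. brain center
    lesion_radius_mm: float | None = None          # None -> solve from target
    brain_semiaxes_mm: tuple[float, float, float] = (6.0, 7.0, 2.0)
    lateral_ventricle_offset_mm: float = 1.0       # +/- x offset of the pair
    lateral_ventricle_semiaxes_mm: tuple[float, float, float] = (0.4, 1.5, 0.8)
    third_ventricle_semiaxes_mm: tuple[float, float, float] = (0.25, 1.0, 0.6)
    third_ventricle_y_offset_mm: float = -1.5
    vessel_tree: tuple[TubeSegment, ...] = field(default_factory=_default_vessel_tree)
    occluded_segments: frozenset[str] = frozenset()
    midline_shift_mm: float = 0.0
    tissue_params: dict[str, TissueParams] = field(default_factory=_default_tissue_params)
    noise_sigma: float = 0.0                       # relative to normal-tissue S0
    seed: int = 0
    vessel_roi_margin_voxels: int = 5

    def validate(self) -> None:
        if any(n <= 0 for n in self.matrix_shape) or len(self.matrix_shape) != 3:
            raise ValueError(f"bad matrix shape {self.matrix_shape}")
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel size must be positive")
        if any(b >= a for b, a in zip(self.te_list_ms, self.te_list_ms[1:])):
            raise ValueError("echo times must be strictly ascending")
        if any(b >= a for b, a in zip(self.b_values, self.b_values[1:])):
            raise ValueError("b-values must be strictly ascending")
        if not 0 <= self.lesion_fraction_target < 1:
            raise ValueError("lesion_fraction_target must be in [0, 1)")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        unknown = set(self.occluded_segments) - set(SEGMENT_LABELS)
        if unknown:
            raise ValueError(f"unknown occluded segments {sorted(unknown)}")
        tp = self.tissue_params
        for name, p in tp.items():
            if p.t2_ms <= 0 or p.adc_mm2_s <= 0:
                raise ValueError(f"tissue {name!r}: T2 and ADC must be positive")
        if not tp["lesion"].t2_ms > tp["normal"].t2_ms:
            raise ValueError("lesion T2 must exceed normal T2")
        if not tp["lesion"].adc_mm2_s < tp["normal"].adc_mm2_s:
            raise ValueError("lesion ADC must be below normal ADC")
        if not tp["csf"].t2_ms > tp["lesion"].t2_ms:
            raise ValueError("CSF T2 must exceed lesion T2")
        if not tp["csf"].adc_mm2_s > tp["normal"].adc_mm2_s:
            raise ValueError("CSF ADC must exceed normal ADC")


@dataclass
class PhantomTruth:
    """Exact voxel-grid ground truth accompanying a generated phantom."""

    brain_mask: np.ndarray
    lesion_mask: np.ndarray
    csf_mask: np.ndarray
    ventricle_mask: np.ndarray
    ipsilateral_mask: np.ndarray
    contralateral_mask: np.ndarray
    true_lesion_fraction: float
    achieved_lesion_radius_mm: float
    true_midline_shift_mm: float
    atlas_midline_x_mm: float
    atlas_ventricle_roi: np.ndarray
    brain_width_mm: float
    segment_masks: dict[str, np.ndarray]
    territory_rois: dict[str, np.ndarray]
    segment_seeds: dict[str, tuple[tuple[int, int, int], tuple[int, int, int]]]
    class_map: np.ndarray
    spacing: tuple[float, float, float]


# -- geometry helpers ---------------------------------------------------------


def _grids(spec: PhantomSpec):
    nx, ny, nz = spec.matrix_shape
    vs = spec.voxel_size_mm
    x = np.arange(nx)[:, None, None] * vs
    y = np.arange(ny)[None, :, None] * vs
    z = np.arange(nz)[None, None, :] * vs
    center = ((nx - 1) / 2 * vs, (ny - 1) / 2 * vs, (nz - 1) / 2 * vs)
    return (x, y, z), center


def _ellipsoid(grids, center, semiaxes) -> np.ndarray:
    x, y, z = grids
    cx, cy, cz = center
    ax, ay, az = semiaxes
    return ((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2 + ((z - cz) / az) ** 2 <= 1.0


def _sphere(grids, center, radius) -> np.ndarray:
    x, y, z = grids
    cx, cy, cz = center
    return (x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2 <= radius**2


def _tube(grids, p0, p1, radius) -> np.ndarray:
    """Voxels whose centers lie within ``radius`` of segment p0-p1."""
    x, y, z = grids
    p0 = np.asarray(p0, dtype=np.float64)
    d = np.asarray(p1, dtype=np.float64) - p0
    L2 = float(d @ d)
    px, py, pz = x - p0[0], y - p0[1], z - p0[2]
    t = (px * d[0] + py * d[1] + pz * d[2]) / L2
    t = np.clip(t, 0.0, 1.0)
    dx = px - t * d[0]
    dy = py - t * d[1]
    dz = pz - t * d[2]
    return dx**2 + dy**2 + dz**2 <= radius**2


# -- construction -------------------------------------------------------------


def _ventricle_mask(spec: PhantomSpec, grids, center, shift: float) -> np.ndarray:
    cx, cy, cz = center
    off = spec.lateral_ventricle_offset_mm
    vents = _ellipsoid(grids, (cx - off + shift, cy, cz), spec.lateral_ventricle_semiaxes_mm)
    vents |= _ellipsoid(grids, (cx + off + shift, cy, cz), spec.lateral_ventricle_semiaxes_mm)
    vents |= _ellipsoid(grids, (cx + shift, cy + spec.third_ventricle_y_offset_mm, cz),
                        spec.third_ventricle_semiaxes_mm)
    return vents


def _lesion_fraction(radius: float, spec: PhantomSpec, grids, center,
                     brain: np.ndarray, vents: np.ndarray, ipsi: np.ndarray):
    if radius <= 0:
        return np.zeros_like(brain), 0.0
    c = tuple(np.asarray(center) + np.asarray(spec.lesion_center_mm))
    lesion = _sphere(grids, c, radius) & brain & ~vents
    hemi = int((brain & ipsi).sum())
    frac = float((lesion & ipsi).sum()) / hemi
    return lesion, frac


def _solve_lesion_radius(spec: PhantomSpec, grids, center, brain, vents, ipsi,
                         r_max: float = 6.0):
    """Bisect the (monotone, stepwise) voxelized fraction to the target."""
    target = spec.lesion_fraction_target
    if target == 0:
        return np.zeros_like(brain), 0.0, 0.0
    _, f_hi = _lesion_fraction(r_max, spec, grids, center, brain, vents, ipsi)
    if f_hi < target:
        lesion, frac = _lesion_fraction(r_max, spec, grids, center, brain, vents, ipsi)
        log.warning("lesion_fraction_target %.3f unreachable for this geometry; "
                    "achieved %.3f at radius %.2f mm", target, frac, r_max)
        return lesion, frac, r_max
    lo, hi = 0.0, r_max
    for _ in range(48):
        mid = 0.5 * (lo + hi)
        _, f = _lesion_fraction(mid, spec, grids, center, brain, vents, ipsi)
        if f < target:
            lo = mid
        else:
            hi = mid
    lesion, frac = _lesion_fraction(hi, spec, grids, center, brain, vents, ipsi)
    return lesion, frac, hi


def _rician(clean: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    if sigma == 0:
        return clean.copy()
    re = clean + rng.normal(0.0, sigma, clean.shape)
    im = rng.normal(0.0, sigma, clean.shape)
    return np.hypot(re, im)


def _seed_voxels(seg: TubeSegment, center, vs, shape):
    p0 = np.asarray(center) + np.asarray(seg.start_mm)
    p1 = np.asarray(center) + np.asarray(seg.end_mm)
    seeds = []
    for t in (0.15, 0.85):
        p = p0 + t * (p1 - p0)
        idx = tuple(int(np.clip(round(c / vs), 0, n - 1)) for c, n in zip(p, shape))
        seeds.append(idx)
    return tuple(seeds)


def generate_phantom(spec: PhantomSpec | None = None, seed: int | None = None):
    """Generate (EchoSeries, DWISeries, TOF QuantVolume, PhantomTruth).

    Identical spec and seed give bit-identical output.  ``seed`` overrides
    ``spec.seed`` when given.
    """
    spec = spec or PhantomSpec()
    spec.validate()
    if seed is None:
        seed = spec.seed
    rng = np.random.default_rng(seed)
    vs = spec.voxel_size_mm
    spacing = (vs, vs, vs)
    grids, center = _grids(spec)
    nx = spec.matrix_shape[0]
    atlas_mid_x = (nx - 1) / 2 * vs

    brain = _ellipsoid(grids, center, spec.brain_semiaxes_mm)
    x = grids[0]
    right = np.broadcast_to(x > atlas_mid_x, spec.matrix_shape)
    ipsi = brain & right
    contra = brain & ~right

    vents = _ventricle_mask(spec, grids, center, spec.midline_shift_mm) & brain
    lesion, frac, radius = (
        _lesion_fraction(spec.lesion_radius_mm, spec, grids, center, brain, vents, ipsi)
        + (spec.lesion_radius_mm,)
        if spec.lesion_radius_mm is not None
        else _solve_lesion_radius(spec, grids, center, brain, vents, ipsi)
    )

    class_map = np.zeros(spec.matrix_shape, dtype=np.uint8)
    class_map[brain] = NORMAL
    class_map[lesion] = LESION
    class_map[vents] = CSF  # ventricles win; lesion is built disjoint anyway

    # per-class parameter fields
    tp = spec.tissue_params
    order = {BACKGROUND: "background", NORMAL: "normal", LESION: "lesion", CSF: "csf"}
    t2 = np.empty(spec.matrix_shape)
    adc = np.empty(spec.matrix_shape)
    s0 = np.empty(spec.matrix_shape)
    tof_base = np.empty(spec.matrix_shape)
    for code, name in order.items():
        sel = class_map == code
        t2[sel] = tp[name].t2_ms
        adc[sel] = tp[name].adc_mm2_s
        s0[sel] = tp[name].s0
        tof_base[sel] = tp[name].tof

    sigma = spec.noise_sigma * tp["normal"].s0

    echo = np.empty(spec.matrix_shape + (len(spec.te_list_ms),))
    for i, te in enumerate(spec.te_list_ms):
        echo[..., i] = _rician(s0 * np.exp(-te / t2), sigma, rng)
    dwi = np.empty(spec.matrix_shape + (len(spec.b_values),))
    for i, b in enumerate(spec.b_values):
        dwi[..., i] = _rician(s0 * np.exp(-b * adc), sigma, rng)

    # TOF: flowing blood is bright in patent tubes only
    segment_masks, territory_rois, segment_seeds = {}, {}, {}
    vessel_bright = np.zeros(spec.matrix_shape, dtype=bool)
    struct = ndi.generate_binary_structure(3, 3)
    for seg in spec.vessel_tree:
        tube = _tube(grids, np.asarray(center) + np.asarray(seg.start_mm),
                     np.asarray(center) + np.asarray(seg.end_mm), seg.radius_mm)
        segment_masks[seg.label] = tube
        territory_rois[seg.label] = ndi.binary_dilation(
            tube, structure=struct, iterations=spec.vessel_roi_margin_voxels)
        segment_seeds[seg.label] = _seed_voxels(seg, center, vs, spec.matrix_shape)
        if seg.label not in spec.occluded_segments:
            vessel_bright |= tube
    # TOF intensities live on their own scale (tissue ~ tp.tof); noise is
    # scaled to the normal-tissue TOF level
    tof = np.where(vessel_bright, 4.0 * tp["normal"].tof, tof_base)
    tof = _rician(tof, spec.noise_sigma * tp["normal"].tof, rng)

    # atlas ventricle ROI: the *unshifted* ventricle geometry, generously
    # dilated, standing in for an atlas mask near the corpus callosum
    atlas_vents = _ventricle_mask(spec, grids, center, 0.0) & brain
    atlas_roi = ndi.binary_dilation(atlas_vents, structure=struct, iterations=8)

    xs = np.nonzero(brain.any(axis=(1, 2)))[0]
    brain_width_mm = float((xs.max() - xs.min() + 1) * vs) if xs.size else 0.0

    truth = PhantomTruth(
        brain_mask=brain,
        lesion_mask=lesion,
        csf_mask=vents,
        ventricle_mask=vents,
        ipsilateral_mask=ipsi,
        contralateral_mask=contra,
        true_lesion_fraction=frac,
        achieved_lesion_radius_mm=float(radius),
        true_midline_shift_mm=float(spec.midline_shift_mm),
        atlas_midline_x_mm=atlas_mid_x,
        atlas_ventricle_roi=atlas_roi,
        brain_width_mm=brain_width_mm,
        segment_masks=segment_masks,
        territory_rois=territory_rois,
        segment_seeds=segment_seeds,
        class_map=class_map,
        spacing=spacing,
    )
    echo_series = EchoSeries(echo, spec.te_list_ms, spacing)
    dwi_series = DWISeries(dwi, spec.b_values, spacing)
    tof_volume = QuantVolume(tof, spacing)
    return echo_series, dwi_series, tof_volume, truth


# -- synthetic cohorts --------------------------------------------------------


@dataclass
class EventRates:
    """Per-stage probabilities for a synthetic cohort.

    Defaults follow the attrition actually observed in a multi-site pilot
    of this model: ~6% procedural death, ~15% death before completing
    treatment, and most post-treatment loss concentrated in the first
    three days.  Compliance violation rates default to the reported ~2%.
    """

    procedural_death: float = 0.0625
    partial_treatment_death: float = 0.148
    death_by_day3: float = 0.20
    death_day3_to_7: float = 0.02
    death_day7_to_30: float = 0.03
    tnk_dose_error: float = 0.02
    tnk_time_error: float = 0.02
    donor_sex_mismatch: float = 0.02
    thrombus_length_error: float = 0.02

    def validate(self) -> None:
        for name, v in self.__dict__.items():
            if not 0 <= v <= 1:
                raise ValueError(f"rate {name}={v} outside [0, 1]")


def generate_cohort(n_per_site: dict[str, int], event_rates: EventRates | None = None,
                    seed: int = 0, donors_per_site: dict[str, int] | None = None,
                    ) -> CohortLedger:
    """Generate a reproducible synthetic event ledger.

    Sex is balanced within each site by alternating M, F, ... so an odd
    count leaves one extra male (the documented rounding rule).  Donors
    are enrolled but never randomized.
    """
    rates = event_rates or EventRates()
    rates.validate()
    rng = np.random.default_rng(seed)
    donors_per_site = donors_per_site or {}
    rows = []
    counter = 0
    for site in sorted(n_per_site):
        n_donor = donors_per_site.get(site, 0)
        for i in range(n_per_site[site] + n_donor):
            counter += 1
            sid = f"C{counter:04d}"
            sex = "M" if i % 2 == 0 else "F"
            if i < n_donor:
                rows += [(sid, site, sex, "donor", "enrolled", 0, "")]
                continue
            events = [("enrolled", 0, ""), ("randomized", 0, ""), ("surgery_start", 0, "")]
            if rng.random() < rates.procedural_death:
                events.append(("died", 0, ""))
            else:
                length = 6.5 if rng.random() < rates.thrombus_length_error \
                    else float(np.clip(rng.normal(5.0, 0.2), 4.5, 6.0))
                events.append(("thrombus_injected", 0, ""))
                events.append(("thrombus_length_cm", 0, f"{length:.2f}"))
                if rng.random() < rates.partial_treatment_death:
                    events.append(("died", 0, ""))
                else:
                    dose = 1.0 if rng.random() < rates.tnk_dose_error else 1.5
                    minutes = 160.0 if rng.random() < rates.tnk_time_error \
                        else float(np.clip(rng.normal(121.0, 2.4), 118.0, 136.0))
                    donor_sex = ("F" if sex == "M" else "M") \
                        if rng.random() < rates.donor_sex_mismatch else sex
                    events += [
                        ("tnk_given", 0.1, ""),
                        ("tnk_dose_mg_per_kg", 0.1, f"{dose:.2f}"),
                        ("minutes_embolism_to_tnk", 0.1, f"{minutes:.1f}"),
                        ("donor_sex", 0.1, donor_sex),
                        ("study_drug_given", 0.12, ""),
                    ]
                    u = rng.random()
                    if u < rates.death_by_day3:
                        events.append(("died", int(rng.integers(1, 4)), ""))
                    elif u < rates.death_by_day3 + rates.death_day3_to_7:
                        events.append(("died", int(rng.integers(4, 8)), ""))
                    elif u < (rates.death_by_day3 + rates.death_day3_to_7
                              + rates.death_day7_to_30):
                        events.append(("died", int(rng.integers(8, 31)), ""))
                    else:
                        events.append(("endpoint_day30", 30, ""))
            for event, day, value in events:
                rows.append((sid, site, sex, "study", event, day, value))
    return CohortLedger(pd.DataFrame(rows, columns=LEDGER_COLUMNS))
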