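"""Shared fixtures: phantoms and pipeline runs are expensive, so the
suite generates them once per session and reuses them."""

from __future__ import annotations

import numpy as np
import pytest

import temcao
from temcao.pipeline import PipelineConfig, SubjectAtlas, analyze_subject


def make_atlas(truth: temcao.PhantomTruth) -> SubjectAtlas:
    return SubjectAtlas(
        atlas_midline_x_mm=truth.atlas_midline_x_mm,
        ventricle_roi=truth.atlas_ventricle_roi,
        territory_rois=truth.territory_rois,
        segment_seeds=truth.segment_seeds,
    )


@pytest.fixture(scope="session")
def noiseless_phantom():
    spec = temcao.PhantomSpec(noise_sigma=0.0)
    return temcao.generate_phantom(spec, seed=11)


@pytest.fixture(scope="session")
def noisy_phantom():
    spec = temcao.PhantomSpec(noise_sigma=0.02)
    return temcao.generate_phantom(spec, seed=11)


@pytest.fixture(scope="session")
def fraction_recovery():
    """Full-pipeline lesion-fraction recovery over a grid of target
    fractions at 2% Rician noise on the full 128x128x30 grid."""
    results = {}
    for target in (0.0, 0.05, 0.13, 0.30):
        spec = temcao.PhantomSpec(noise_sigma=0.02, lesion_fraction_target=target)
        echo, dwi, tof, truth = temcao.generate_phantom(spec, seed=23)
        res = analyze_subject(echo, dwi, make_atlas(truth),
                              config=PipelineConfig(resample=False))
        results[target] = {
            "truth": truth.true_lesion_fraction,
            "estimate": res.metrics["lesion_volume_fraction"],
            "midline_shift_mm": res.metrics["midline_shift_mm"],
        }
    return results


@pytest.fixture(scope="session")
def shifted_midline_result():
    """Pipeline run on a phantom with a +0.6 mm ventricle displacement."""
    spec = temcao.PhantomSpec(noise_sigma=0.02, midline_shift_mm=0.6)
    echo, dwi, tof, truth = temcao.generate_phantom(spec, seed=29)
    res = analyze_subject(echo, dwi, make_atlas(truth),
                          config=PipelineConfig(resample=False))
    return truth, res


def flood_fill_hysteresis(score: np.ndarray, weak: float, strong: float) -> np.ndarray:
    """Brute-force oracle: BFS from strong voxels through the weak set,
    26-connectivity (all neighbors differing by at most 1 per axis)."""
    strong_mask = score >= strong
    weak_mask = score >= weak
    out = np.zeros(score.shape, dtype=bool)
    stack = [tuple(idx) for idx in np.argwhere(strong_mask)]
    offsets = [np.array(d) for d in np.ndindex((3,) * score.ndim)
               if any(x != 1 for x in d)]
    offsets = [d - 1 for d in offsets]
    while stack:
        p = stack.pop()
        if out[p]:
            continue
        out[p] = True
        for d in offsets:
            q = tuple(np.array(p) + d)
            if all(0 <= qi < n for qi, n in zip(q, score.shape)):
                if weak_mask[q] and not out[q]:
                    stack.append(q)
    return out
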