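"""Vessel extraction: contrast stretch, Frangi tubularity, binarization,
meshing, segment continuity and occlusion classification."""

import itertools

import numpy as np
import pytest

import temcao
from temcao import QuantVolume
from temcao.angio import (AngioConfig, assess_segments, binarize_vessels,
                          classify_occlusion, enhance_tof, frangi_vesselness,
                          mesh_vessels, run_angio)

ISO = (0.15, 0.15, 0.15)


def _cylinder(shape=(32, 32, 32), radius=2.0, axis=2, value=1.0):
    idx = np.indices(shape)
    others = [i for i in range(3) if i != axis]
    c = [(shape[i] - 1) / 2 for i in range(3)]
    r2 = sum((idx[i] - c[i]) ** 2 for i in others)
    return np.where(r2 <= radius**2, value, 0.0)


class TestEnhance:
    def test_constant_unchanged_with_warning(self, caplog):
        vol = QuantVolume(np.full((8, 8, 8), 3.0), ISO)
        out = enhance_tof(vol)
        assert np.allclose(out.data, 3.0)
        assert "constant" in caplog.text

    def test_linear_ramp_stretched_to_unit_range(self):
        data = np.linspace(0, 10, 16**3).reshape(16, 16, 16)
        out = enhance_tof(QuantVolume(data, ISO))
        assert out.data.min() == 0.0
        assert out.data.max() == 1.0

    def test_monotone_rank_preserving(self):
        rng = np.random.default_rng(0)
        data = rng.random((12, 12, 12))
        out = enhance_tof(QuantVolume(data, ISO)).data
        a, b = data.ravel(), out.ravel()
        order = np.argsort(a)
        assert (np.diff(b[order]) >= -1e-12).all()


class TestFrangi:
    def test_tube_axis_dominates_background(self):
        vol = QuantVolume(_cylinder(radius=2.0), ISO)
        v = frangi_vesselness(vol, AngioConfig(frangi_scales=(2.0,)))
        axis = v.data[15:17, 15:17, 8:24].mean()
        background = np.median(v.data[:8, :8, :])
        assert axis > 10 * (background + 1e-9)

    def test_blob_suppressed_relative_to_tube(self):
        # equal-radius sphere and cylinder in one volume, so both see the
        # same normalization: the blob must respond weaker than the tube axis
        shape = (48, 48, 48)
        idx = np.indices(shape)
        data = np.where((idx[0] - 12.0) ** 2 + (idx[1] - 12.0) ** 2 <= 4.0**2,
                        1.0, 0.0)  # cylinder along z at (12, 12)
        r2 = sum((idx[i] - c) ** 2 for i, c in zip(range(3), (34.0, 34.0, 24.0)))
        data[r2 <= 4.0**2] = 1.0   # sphere at (34, 34, 24)
        cfg = AngioConfig(frangi_scales=(4.0,), contrast_threshold=0.0)
        v = frangi_vesselness(QuantVolume(data, ISO), cfg).data
        sphere_center = v[32:37, 32:37, 22:27].max()
        axis = v[11:14, 11:14, 20:28].max()
        assert sphere_center < 0.5 * axis

    def test_all_zero_volume_gives_zero_vesselness(self):
        v = frangi_vesselness(QuantVolume(np.zeros((16, 16, 16)), ISO))
        assert (v.data == 0).all()

    def test_values_in_unit_interval(self, noisy_phantom):
        _, _, tof, _ = noisy_phantom
        v = frangi_vesselness(enhance_tof(tof))
        assert v.data.min() >= 0.0 and v.data.max() <= 1.0

    def test_grid_axis_rotation_equivariance(self):
        vol = _cylinder(radius=2.0, axis=2)
        rotated = np.transpose(vol, (2, 0, 1))  # tube now along axis 0
        cfg = AngioConfig(frangi_scales=(2.0,))
        v0 = frangi_vesselness(QuantVolume(vol, ISO), cfg).data
        v1 = frangi_vesselness(QuantVolume(rotated, ISO), cfg).data
        assert np.allclose(np.sort(v0.ravel()), np.sort(v1.ravel()), atol=1e-9)

    def test_oversized_scale_rejected(self):
        with pytest.raises(ValueError):
            frangi_vesselness(QuantVolume(np.ones((8, 8, 8)), ISO),
                              AngioConfig(frangi_scales=(10.0,)))


class TestBinarize:
    def test_empty_vesselness_gives_empty_mask(self):
        assert not binarize_vessels(QuantVolume(np.zeros((8, 8, 8)), ISO)).any()

    def test_threshold_one_keeps_only_max(self):
        rng = np.random.default_rng(1)
        v = QuantVolume(rng.random((8, 8, 8)), ISO)
        mask = binarize_vessels(v, AngioConfig(binarize_threshold=1.0,
                                               min_component_voxels=1))
        assert mask.sum() == 1

    def test_phantom_tree_axis_coverage(self, noiseless_phantom):
        # vessel mask should cover nearly all tube-axis voxels
        from temcao.phantom import PhantomSpec, _grids
        _, _, tof, truth = noiseless_phantom
        res = run_angio(tof, truth.territory_rois, truth.segment_seeds)
        spec = PhantomSpec()
        _, center = _grids(spec)
        vs = spec.voxel_size_mm
        covered, total = 0, 0
        for seg in spec.vessel_tree:
            p0 = np.asarray(center) + np.asarray(seg.start_mm)
            p1 = np.asarray(center) + np.asarray(seg.end_mm)
            for t in np.linspace(0.1, 0.9, 40):
                idx = tuple(int(round(c / vs)) for c in p0 + t * (p1 - p0))
                total += 1
                covered += bool(res.vessel_mask[idx])
        assert covered / total >= 0.9


class TestMesh:
    def test_single_voxel_is_topological_sphere(self):
        mask = np.zeros((5, 5, 5), bool)
        mask[2, 2, 2] = True
        mesh = mesh_vessels(mask, ISO)
        assert not mesh.is_empty
        assert mesh.euler_characteristic() == 2

    def test_empty_mask_gives_empty_mesh(self):
        mesh = mesh_vessels(np.zeros((4, 4, 4), bool), ISO)
        assert mesh.is_empty
        assert mesh.surface_area() == 0.0

    def test_cylinder_area_and_volume_against_analytic(self):
        spacing = (1.0, 1.0, 1.0)
        shape, radius = (40, 40, 40), 6.0
        mask = _cylinder(shape, radius=radius) > 0
        mesh = mesh_vessels(mask, spacing)
        # analytic cylinder: height spans the full grid
        height = shape[2]
        # voxelized radius: effective radius from the voxel count
        r_eff = np.sqrt(mask[:, :, 0].sum() / np.pi)
        area_true = 2 * np.pi * r_eff * height + 2 * np.pi * r_eff**2
        assert mesh.surface_area() == pytest.approx(area_true, rel=0.15)
        assert mesh.enclosed_volume() == pytest.approx(mask.sum(), rel=0.10)

    def test_mesh_volume_matches_phantom_mask(self, noiseless_phantom):
        _, _, tof, truth = noiseless_phantom
        res = run_angio(tof, truth.territory_rois, truth.segment_seeds)
        voxel = np.prod(ISO)
        assert res.mesh.enclosed_volume() == pytest.approx(
            res.vessel_mask.sum() * voxel, rel=0.10)


def _union_find_connected(mask, a, b):
    """Independent oracle: union-find over 26-connected voxel pairs."""
    idx = {tuple(p): i for i, p in enumerate(np.argwhere(mask))}
    parent = list(range(len(idx)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for p, i in idx.items():
        for d in itertools.product((-1, 0, 1), repeat=3):
            if d == (0, 0, 0):
                continue
            q = tuple(np.add(p, d))
            j = idx.get(q)
            if j is not None:
                parent[find(i)] = find(j)
    if a not in idx or b not in idx:
        return False
    return find(idx[a]) == find(idx[b])


class TestSegments:
    def test_patent_phantom_all_present(self, noiseless_phantom):
        _, _, tof, truth = noiseless_phantom
        res = run_angio(tof, truth.territory_rois, truth.segment_seeds)
        assert all(res.segment_presence.values())
        assert res.occlusion_class == "none"

    def test_occluded_mca_detected(self):
        spec = temcao.PhantomSpec(noise_sigma=0.02,
                                  occluded_segments=frozenset({"MCA"}))
        _, _, tof, truth = temcao.generate_phantom(spec, seed=5)
        res = run_angio(tof, truth.territory_rois, truth.segment_seeds)
        assert res.segment_presence["MCA"] is False
        assert all(v for k, v in res.segment_presence.items() if k != "MCA")
        assert res.occlusion_class == "MCA"

    def test_empty_mask_all_absent(self):
        shape = (8, 8, 8)
        rois = {"MCA": np.ones(shape, bool)}
        seeds = {"MCA": ((1, 1, 1), (6, 6, 6))}
        presence = assess_segments(np.zeros(shape, bool), rois, seeds)
        assert presence == {"MCA": False}

    def test_seed_outside_volume_rejected(self):
        shape = (8, 8, 8)
        with pytest.raises(ValueError, match="outside"):
            assess_segments(np.ones(shape, bool), {"X": np.ones(shape, bool)},
                            {"X": ((0, 0, 0), (9, 0, 0))})

    def test_matches_union_find_oracle_on_random_masks(self):
        rng = np.random.default_rng(7)
        shape = (16, 16, 16)
        roi = np.ones(shape, bool)
        for trial in range(15):
            mask = rng.random(shape) < 0.25
            a = tuple(rng.integers(0, 16, 3))
            b = tuple(rng.integers(0, 16, 3))
            got = assess_segments(mask, {"S": roi}, {"S": (a, b)})["S"]
            want = mask[a] and mask[b] and _union_find_connected(mask, a, b)
            assert got == bool(want), (trial, a, b)


class TestClassify:
    def test_exhaustive_truth_table(self):
        for bits in itertools.product([True, False], repeat=4):
            mca, aca, pca, ica = bits
            got = classify_occlusion({"MCA": mca, "ACA": aca, "PCA": pca,
                                      "distal_ICA": ica})
            if not mca and not ica:
                assert got == "T_occlusion"
            elif not mca and not aca:
                assert got == "MCA_ACA"
            elif not mca:
                assert got == "MCA"
            elif not ica:
                assert got == "distal_ICA"
            elif aca and pca:
                assert got == "none"
            else:
                assert got == "other"
            # structural invariants
            assert (got == "none") == all(bits)
            assert (got == "T_occlusion") == (not mca and not ica)

    def test_unassessable_is_explicit_unknown(self):
        assert classify_occlusion({"MCA": True, "ACA": None, "PCA": True,
                                   "distal_ICA": True}) == "unknown"
        assert classify_occlusion({"MCA": True}) == "unknown"

    def test_ica_alias_accepted(self):
        assert classify_occlusion({"MCA": False, "ACA": True, "PCA": True,
                                   "ICA": False}) == "T_occlusion"
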