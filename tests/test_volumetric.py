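"""Rigid registration, resampling, subtraction, segmentation, VOI
statistics and morphometry."""

import numpy as np
import pytest

from cartidiff.containers import VoiSpec, VolumeImage
from cartidiff.synthetic.phantom import build_ct_phantom_pair
from cartidiff.volumetric import (
    RigidTransform,
    estimate_cartilage_thickness,
    estimate_cartilage_volume,
    fit_rigid_from_fiducials,
    map_iodine,
    resample_volume,
    segment_iodine_mask,
    subtract_volumes,
    voi_statistics,
)

TETRA = np.array(
    [[0.0, 0.0, 0.0], [20.0, 2.0, 3.0], [3.0, 22.0, 5.0], [6.0, 7.0, 25.0]]
)


class TestRigidTransform:
    def test_reflection_rejected(self):
        refl = np.diag([1.0, 1.0, -1.0])
        with pytest.raises(ValueError, match="proper"):
            RigidTransform(refl, np.zeros(3))

    def test_non_orthonormal_rejected(self):
        with pytest.raises(ValueError, match="orthonormal"):
            RigidTransform(np.eye(3) * 1.01, np.zeros(3))

    def test_compose_with_inverse_is_identity(self):
        t = RigidTransform.from_euler((20, -10, 5), (1.0, 2.0, -3.0))
        ident = t.compose(t.inverse())
        assert np.allclose(ident.rotation, np.eye(3), atol=1e-12)
        assert np.allclose(ident.translation, 0.0, atol=1e-12)


class TestFitRigid:
    def test_identity_on_equal_points(self):
        fit, rms = fit_rigid_from_fiducials(TETRA, TETRA)
        assert np.allclose(fit.rotation, np.eye(3), atol=1e-12)
        assert np.allclose(fit.translation, 0.0, atol=1e-12)
        assert rms < 1e-12

    def test_recovers_90deg_rotation_plus_shift(self):
        true = RigidTransform.from_euler((0, 0, 90), (1.0, 2.0, 3.0))
        fit, rms = fit_rigid_from_fiducials(TETRA, true.apply(TETRA))
        assert np.allclose(fit.rotation, true.rotation, atol=1e-9)
        assert np.allclose(fit.translation, true.translation, atol=1e-9)
        assert rms < 1e-9

    def test_noisy_markers_monte_carlo(self):
        true = RigidTransform.from_euler((3, -2, 4), (1.0, -0.5, 2.0))
        rng = np.random.default_rng(21)
        rot_errs, rmss = [], []
        for _ in range(200):
            dst = true.apply(TETRA) + rng.normal(0, 0.1, TETRA.shape)
            fit, rms = fit_rigid_from_fiducials(TETRA, dst)
            rot_errs.append(fit.compose(true.inverse()).rotation_angle_deg())
            rmss.append(rms)
        assert np.median(rot_errs) < 1.0
        assert 0.02 < np.median(rmss) < 0.3  # on the marker-noise scale

    def test_collinear_and_mismatched_rejected(self):
        line = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]], dtype=float)
        with pytest.raises(ValueError, match="collinear"):
            fit_rigid_from_fiducials(line, line)
        with pytest.raises(ValueError, match="mismatch"):
            fit_rigid_from_fiducials(TETRA, TETRA[:3])


class TestResample:
    def _smooth_volume(self, shape=(24, 20, 16)):
        x, y, z = np.indices(shape, dtype=float)
        vox = np.sin(x / 4.0) + np.cos(y / 5.0) + 0.3 * z / shape[2]
        return VolumeImage(vox, voxel_size=(1.0, 1.0, 1.0))

    def test_identity_is_exact(self):
        vol = self._smooth_volume()
        out = resample_volume(vol, RigidTransform.identity())
        assert np.allclose(out.voxels, vol.voxels, atol=1e-12)

    def test_one_voxel_lattice_shift(self):
        vol = self._smooth_volume()
        shift = RigidTransform(np.eye(3), np.array([1.0, 0.0, 0.0]))
        out = resample_volume(vol, shift)
        assert np.allclose(out.voxels[:-1], vol.voxels[1:], atol=1e-12)
        assert not out.valid[-1].any()  # sampled beyond the far face

    def test_round_trip_error_bounded_by_curvature(self):
        vol = self._smooth_volume()
        t = RigidTransform.from_euler((0, 0, 7), (0.4, -0.3, 0.2))
        back = resample_volume(resample_volume(vol, t), t.inverse())
        ok = back.valid
        # trilinear round trip errs at most on the scale of the local second
        # difference; for this smooth field that is ~ h^2 * |f''| ~ 0.13
        err = np.abs(back.voxels - vol.voxels)[ok]
        assert err.max() < 0.13


class TestSubtractSegment:
    def test_identical_volumes_zero(self):
        vol = VolumeImage(np.ones((6, 6, 6)), (1, 1, 1))
        diff = subtract_volumes(vol, vol)
        assert np.all(diff.voxels == 0.0)

    def test_grid_mismatch_rejected(self):
        a = VolumeImage(np.ones((6, 6, 6)), (1, 1, 1))
        b = VolumeImage(np.ones((6, 6, 5)), (1, 1, 1))
        with pytest.raises(ValueError, match="mismatch"):
            subtract_volumes(a, b)

    def test_zero_difference_gives_empty_mask(self):
        diff = VolumeImage(np.zeros((8, 8, 8)), (1, 1, 1))
        assert not segment_iodine_mask(diff, threshold_hu=10.0).any()

    def test_clean_phantom_mask_equals_label(self):
        pair = build_ct_phantom_pair(
            shape=(48, 40, 24), noise_sd_hu=0.0,
            transform_params={"angles_deg": (0, 0, 0), "translation_mm": (0, 0, 0)},
        )
        diff = subtract_volumes(pair.post, pair.pre)
        mask = segment_iodine_mask(diff, threshold_hu=100.0, min_component_voxels=1)
        assert np.array_equal(mask, pair.cartilage_mask)

    def test_small_components_removed(self):
        vox = np.zeros((12, 12, 12))
        vox[2:8, 2:8, 2:8] = 50.0  # 216-voxel block survives
        vox[10, 10, 10] = 50.0  # isolated speckle removed
        diff = VolumeImage(vox, (1, 1, 1))
        mask = segment_iodine_mask(diff, threshold_hu=25.0, min_component_voxels=27)
        assert mask[3, 3, 3]
        assert not mask[10, 10, 10]


class TestVoiStatistics:
    def test_constant_volume(self):
        vol = VolumeImage(np.full((32, 32, 16), 4.0), (1, 1, 1))
        vois = [VoiSpec(center=(16, 16, 8), radius=5, half_length=4, axis=2)]
        table, pooled = voi_statistics(vol, vois)
        assert table.loc[0, "mean"] == 4.0
        assert table.loc[0, "sd"] == 0.0
        assert pooled["mean"] == 4.0

    def test_count_matches_bruteforce(self):
        vol = VolumeImage(np.zeros((40, 40, 20)), (1, 1, 1))
        vois = [
            VoiSpec(center=(cx, cy, 9.0), radius=5.0, half_length=4.0, axis=2)
            for cx in (10.0, 20.0, 30.0)
            for cy in (10.0, 25.0)
        ]
        table, _ = voi_statistics(vol, vois)
        for i, voi in enumerate(vois):
            brute = sum(
                1
                for x in range(40)
                for y in range(40)
                for z in range(20)
                if (x - voi.center[0]) ** 2 + (y - voi.center[1]) ** 2
                <= voi.radius**2
                and abs(z - voi.center[2]) <= voi.half_length
            )
            assert table.loc[i, "n"] == brute

    def test_empty_list_ok(self):
        vol = VolumeImage(np.zeros((8, 8, 8)), (1, 1, 1))
        table, pooled = voi_statistics(vol, [])
        assert len(table) == 0
        assert pooled["n"] == 0

    def test_out_of_bounds_rejected(self):
        vol = VolumeImage(np.zeros((16, 16, 8)), (1, 1, 1))
        with pytest.raises(ValueError, match="outside"):
            voi_statistics(
                vol, [VoiSpec(center=(15, 8, 4), radius=5, half_length=2, axis=2)]
            )


class TestMapIodine:
    def test_delta_equal_intercept_maps_to_zero(self, clinical_calibration):
        vox = np.full((6, 6, 6), clinical_calibration.a)
        diff = VolumeImage(vox, (1, 1, 1), units="delta-HU")
        mask = np.ones((6, 6, 6), dtype=bool)
        conc = map_iodine(diff, clinical_calibration, mask)
        assert np.allclose(conc.voxels, 0.0, atol=1e-12)

    def test_forward_inverse_consistency_on_phantom(self, clinical_calibration):
        pair = build_ct_phantom_pair(
            shape=(48, 40, 24), noise_sd_hu=0.0,
            transform_params={"angles_deg": (0, 0, 0), "translation_mm": (0, 0, 0)},
        )
        diff = subtract_volumes(pair.post, pair.pre)
        conc = map_iodine(diff, clinical_calibration, pair.cartilage_mask)
        assert np.allclose(conc.voxels[pair.cartilage_mask], 10.0, atol=1e-9)

    def test_masked_out_voxels_invalid(self, clinical_calibration):
        diff = VolumeImage(np.full((4, 4, 4), 100.0), (1, 1, 1))
        mask = np.zeros((4, 4, 4), dtype=bool)
        mask[1, 1, 1] = True
        conc = map_iodine(diff, clinical_calibration, mask)
        assert conc.valid.sum() == 1

    def test_gl_calibration_rejected(self, micro_calibration):
        diff = VolumeImage(np.zeros((4, 4, 4)), (1, 1, 1))
        with pytest.raises(ValueError, match="HU"):
            map_iodine(diff, micro_calibration, np.ones((4, 4, 4), dtype=bool))


class TestMorphometry:
    def test_volume_arithmetic(self):
        mask = np.zeros((20, 20, 20), dtype=bool)
        mask.flat[:1000] = True
        assert estimate_cartilage_volume(mask, (0.32, 0.32, 0.625)) == pytest.approx(
            0.064
        )
        assert estimate_cartilage_volume(np.zeros((4, 4, 4), bool), (1, 1, 1)) == 0.0

    def test_volume_invariant_under_lattice_shift(self):
        mask = np.zeros((20, 20, 20), dtype=bool)
        mask[5:12, 6:14, 3:9] = True
        shifted = np.roll(mask, (2, -1, 3), axis=(0, 1, 2))
        vs = (0.32, 0.32, 0.625)
        assert estimate_cartilage_volume(mask, vs) == estimate_cartilage_volume(
            shifted, vs
        )

    def test_uniform_slab_thickness(self):
        mask = np.zeros((30, 16, 16), dtype=bool)
        mask[10:17] = True  # 7 voxels thick along axis 0
        mean, sd, _ = estimate_cartilage_thickness(mask, None, axis=0, pixel_size=0.32)
        assert mean == pytest.approx(2.24)
        assert sd == pytest.approx(0.0, abs=1e-12)

    def test_empty_mask_thickness_zero(self):
        mean, _, _ = estimate_cartilage_thickness(
            np.zeros((8, 8, 8), bool), None, axis=0, pixel_size=0.32
        )
        assert mean == 0.0

    def test_longest_run_ignores_speckle(self):
        mask = np.zeros((30, 4, 4), dtype=bool)
        mask[5:12, :, :] = True
        mask[20, :, :] = True  # detached speckle above the slab
        mean, _, _ = estimate_cartilage_thickness(mask, None, axis=0, pixel_size=1.0)
        assert mean == pytest.approx(7.0)

    def test_phantom_thickness_tracks_generator_truth(self, small_phantom):
        mask = small_phantom.cartilage_mask
        vois = [
            VoiSpec(center=(32.0, cy, cz), radius=4.0, half_length=28.0, axis=0)
            for cy in (14.0, 30.0)
            for cz in (10.0, 20.0)
        ]
        mean, _, per_voi = estimate_cartilage_thickness(
            mask, vois, axis=0, pixel_size=small_phantom.pre.voxel_size[0]
        )
        true = small_phantom.true_thickness_mm()
        for voi, est in zip(vois, per_voi):
            cy, cz = int(voi.center[1]), int(voi.center[2])
            local = true[cy - 4 : cy + 5, cz - 4 : cz + 5]
            local = local[local > 0]
            assert abs(est - local.mean()) <= 0.5 * small_phantom.pre.voxel_size[0]
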