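import numpy as np
import pytest
from scipy.ndimage import distance_transform_edt

from breastfem.volume import Label
from breastfem.phantom import (PhantomSpec, make_supine_phantom,
                               make_prone_ground_truth)
from breastfem import fem
from breastfem.imageproc import breast_volume_and_density


def brute_force_location_ratio(case):
    """Distance-transform oracle for the lesion depth ratio.

    Distance of the lesion centroid to the chest-wall plane divided by the
    largest distance of any breast-surface voxel to that plane, both
    measured voxel-wise — independent of the evaluate module.
    """
    labels = case.labels_supine
    breast = labels.breast_mask()
    # surface voxels: breast voxels adjacent to non-breast
    dist_in = distance_transform_edt(breast)
    surface = breast & (dist_in <= 1.0)
    idx = np.argwhere(surface)
    world_y = labels.origin[1] + idx[:, 1] * labels.spacing[1]
    d_far = world_y.max()
    d_lesion = case.lesion_centroid_supine[1]
    return d_lesion / d_far


class TestSupinePhantom:
    def test_determinism_bit_identical(self, small_spec):
        a = make_supine_phantom(small_spec)
        b = make_supine_phantom(small_spec)
        np.testing.assert_array_equal(a.ct_supine.data, b.ct_supine.data)
        np.testing.assert_array_equal(a.pet_supine.data, b.pet_supine.data)
        np.testing.assert_array_equal(a.labels_supine.data,
                                      b.labels_supine.data)
        np.testing.assert_array_equal(a.nipple_supine, b.nipple_supine)

    def test_different_seeds_differ(self, small_spec):
        import dataclasses
        other = dataclasses.replace(small_spec, seed=small_spec.seed + 1)
        a = make_supine_phantom(small_spec)
        b = make_supine_phantom(other)
        assert not np.array_equal(a.ct_supine.data, b.ct_supine.data)

    @pytest.mark.parametrize("target", [0.15, 0.27])
    def test_density_presets_achieved(self, target):
        spec = PhantomSpec(breast_radius=24.0, volumetric_density_target=target,
                           seed=7)
        case = make_supine_phantom(spec)
        _, dens = breast_volume_and_density(case.labels_supine)
        assert abs(dens - target) <= 0.02

    def test_density_and_ratio_over_random_specs(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            spec = PhantomSpec(
                breast_radius=float(rng.uniform(20, 30)),
                volumetric_density_target=float(rng.uniform(0.08, 0.45)),
                lesion_radius=4.0,
                lesion_location_ratio_target=float(rng.uniform(0.35, 0.7)),
                seed=int(rng.integers(1 << 31)))
            case = make_supine_phantom(spec)
            _, dens = breast_volume_and_density(case.labels_supine)
            assert abs(dens - spec.volumetric_density_target) <= 0.02
            ratio = brute_force_location_ratio(case)
            assert abs(ratio - spec.lesion_location_ratio_target) <= 0.08

    def test_lesion_ratio_against_distance_transform_oracle(self, small_case):
        ratio = brute_force_location_ratio(small_case)
        assert abs(ratio
                   - small_case.truth.lesion_location_ratio_target) <= 0.05

    def test_nipple_on_breast_surface(self, small_case):
        labels = small_case.labels_supine
        R = small_case.truth.breast_radius
        assert np.linalg.norm(small_case.nipple_supine) == pytest.approx(R)
        # voxel at the nipple (just inside) is breast
        inside = small_case.nipple_supine * (1 - 1.5 * labels.spacing[1] / R)
        idx = np.rint(labels.world_to_index(inside)).astype(int)
        assert labels.data[tuple(idx)] in (Label.ADIPOSE,
                                           Label.FIBROGLANDULAR)

    def test_chest_landmarks_on_wall_plane(self, small_case):
        assert np.allclose(small_case.chest_wall_landmarks[:, 1], 0.0)
        # non-collinear
        p = small_case.chest_wall_landmarks
        n = np.cross(p[1] - p[0], p[2] - p[0])
        assert np.linalg.norm(n) > 1.0

    def test_pet_lesion_hot_and_blurry(self, small_case):
        pet = small_case.pet_supine.data
        lesion = small_case.labels_supine.mask(Label.LESION)
        assert pet[lesion].mean() > 3 * pet[small_case.labels_supine.mask(
            Label.ADIPOSE)].mean()

    def test_oversized_lesion_rejected(self):
        with pytest.raises(ValueError, match="does not fit"):
            PhantomSpec(breast_radius=20.0, lesion_radius=12.0,
                        lesion_location_ratio_target=0.5)

    def test_invalid_density_rejected(self):
        with pytest.raises(ValueError):
            PhantomSpec(volumetric_density_target=0.0)


class TestProneGroundTruth:
    @pytest.fixture(scope="class")
    def prone_case(self, small_case, fast_fem_config):
        return make_prone_ground_truth(small_case,
                                       fem_config=fast_fem_config,
                                       element_size=4.0)

    def test_zero_gravity_prone_equals_supine(self, small_case):
        cfg = fem.FemConfig(gravity_magnitude=0.0)
        out = make_prone_ground_truth(small_case, fem_config=cfg,
                                      element_size=4.0)
        np.testing.assert_allclose(out.mr_prone.data,
                                   out.ct_supine.data, atol=1e-9)
        np.testing.assert_allclose(out.nipple_prone, out.nipple_supine,
                                   atol=1e-9)

    def test_prone_nipple_moves_anteriorly(self, prone_case):
        assert prone_case.forward_nipple_displacement > 1.0
        assert prone_case.nipple_prone[1] > prone_case.nipple_supine[1]

    def test_softer_truth_sags_more(self, small_case, prone_case,
                                    fast_fem_config):
        import dataclasses
        stiff_spec = dataclasses.replace(
            small_case.truth,
            true_E_adipose=2 * small_case.truth.true_E_adipose)
        stiff_case = dataclasses.replace(small_case, truth=stiff_spec)
        firm = make_prone_ground_truth(stiff_case, fem_config=fast_fem_config,
                                       element_size=4.0)
        assert (prone_case.forward_nipple_displacement
                > firm.forward_nipple_displacement)

    def test_lesion_centroid_matches_warped_mask_centroid(self, prone_case):
        # brute force: advect every lesion voxel through the dense field and
        # take the centroid
        labels = prone_case.labels_supine
        field = prone_case.forward_field
        idx = np.argwhere(labels.mask(Label.LESION))
        pts = labels.origin + idx * labels.spacing
        from breastfem.register import _sample_field
        moved = pts + _sample_field(field, pts)
        voxel = float(labels.spacing.max())
        err = np.linalg.norm(moved.mean(axis=0)
                             - prone_case.lesion_centroid_prone)
        assert err <= 0.5 * voxel

    def test_lesion_mass_conserved_in_warp(self, prone_case):
        # near-incompressibility: the warped lesion volume changes < 5%.
        # Partial-volume (float-mask) counting, so hard-threshold rounding
        # of a few-voxel lesion does not masquerade as volume change.
        from breastfem.volume import Volume
        from breastfem.register import warp_volume
        labels = prone_case.labels_supine
        mask = labels.mask(Label.LESION).astype(float)
        vol = Volume(data=mask, spacing=labels.spacing.copy(),
                     origin=labels.origin.copy())
        warped = warp_volume(vol, prone_case.forward_field,
                             direction="forward")
        assert warped.data.sum() == pytest.approx(mask.sum(), rel=0.05)

    def test_save_round_trip(self, prone_case, tmp_path):
        import json
        prone_case.save(tmp_path / "case")
        meta = json.loads((tmp_path / "case" / "landmarks.json").read_text())
        assert meta["truth"]["true_E_adipose"] == prone_case.truth.true_E_adipose
        assert (tmp_path / "case" / "mr_prone.nii.gz").exists()
        from breastfem.volume import Volume
        mr = Volume.load(tmp_path / "case" / "mr_prone.nii.gz")
        assert mr.shape == prone_case.mr_prone.shape
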