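import numpy as np
import pytest

from breastfem.volume import Volume, LabelMap, Label
from breastfem.imageproc import (resample_isotropic, crop_breast, fcm_segment,
                                 breast_volume_and_density)


def make_volume(data, spacing, origin=(0, 0, 0)):
    return Volume(data=np.asarray(data, float), spacing=spacing,
                  origin=np.asarray(origin, float))


class TestResample:
    def test_identity_at_target_spacing(self):
        rng = np.random.default_rng(0)
        v = make_volume(rng.normal(size=(8, 9, 10)), [1, 1, 1])
        out = resample_isotropic(v, 1.0)
        assert out.shape == v.shape
        np.testing.assert_array_equal(out.data, v.data)

    def test_trilinear_reproduces_affine_field(self):
        # an intensity that is affine in world position is reproduced
        # exactly by trilinear interpolation at any grid
        sp = np.array([2.0, 3.0, 1.5])
        idx = np.indices((10, 8, 12)).astype(float)
        world = idx * sp[:, None, None, None]
        data = 2.0 + 0.5 * world[0] - 1.25 * world[1] + 3.0 * world[2]
        v = make_volume(data, sp)
        out = resample_isotropic(v, 1.0)
        oidx = np.indices(out.shape).astype(float)
        expected = 2.0 + 0.5 * oidx[0] - 1.25 * oidx[1] + 3.0 * oidx[2]
        np.testing.assert_allclose(out.data, expected, atol=1e-9)

    def test_extent_preserved(self):
        v = make_volume(np.zeros((50, 50, 50)), [2, 2, 2])
        out = resample_isotropic(v, 1.0)
        # 2 mm spacing, 50 voxels: 98 mm centre-to-centre extent -> 99 voxels
        assert out.shape == (99, 99, 99)
        old_extent = (np.array(v.shape) - 1) * v.spacing
        new_extent = (np.array(out.shape) - 1) * out.spacing
        assert np.all(np.abs(old_extent - new_extent) <= 1.0)

    def test_round_trip_error_second_order(self):
        # resampling down and back reproduces a smooth field to O(h^2)
        n = 24
        idx = np.indices((n, n, n)).astype(float) / n
        smooth = np.sin(2 * np.pi * idx[0]) * np.cos(np.pi * idx[1]) + idx[2]
        v = make_volume(smooth, [2, 2, 2])
        down = resample_isotropic(v, 1.0)
        back = resample_isotropic(down, 2.0)
        inner = (slice(2, -2),) * 3
        err = np.abs(back.data[inner] - v.data[inner]).max()
        assert err < 0.02

    def test_nonfinite_rejected(self):
        v = make_volume(np.full((4, 4, 4), np.nan), [1, 1, 1])
        with pytest.raises(ValueError):
            resample_isotropic(v, 1.0)


class TestCrop:
    def test_full_mask_zero_margin_identity(self):
        v = make_volume(np.arange(4 * 4 * 4.0).reshape(4, 4, 4), [1, 1, 1])
        lab = LabelMap(data=np.full((4, 4, 4), int(Label.ADIPOSE)),
                       spacing=[1, 1, 1])
        vc, lc = crop_breast(v, lab, margin=0.0)
        np.testing.assert_array_equal(vc.data, v.data)
        assert vc.shape == lc.data.shape

    def test_single_voxel_margin_box(self):
        lab = np.zeros((21, 21, 21), dtype=np.int64)
        lab[10, 10, 10] = Label.ADIPOSE
        v = make_volume(np.zeros((21, 21, 21)), [1, 1, 1])
        vc, lc = crop_breast(v, LabelMap(data=lab, spacing=[1, 1, 1]), margin=5.0)
        assert vc.shape == (11, 11, 11)
        assert lc.data[5, 5, 5] == Label.ADIPOSE
        # origin shifted to the crop corner
        np.testing.assert_allclose(vc.origin, [5, 5, 5])

    def test_margin_clamped_at_bounds(self):
        lab = np.zeros((6, 6, 6), dtype=np.int64)
        lab[1:5, 1:5, 1:5] = Label.ADIPOSE
        v = make_volume(np.zeros((6, 6, 6)), [1, 1, 1])
        vc, _ = crop_breast(v, LabelMap(data=lab, spacing=[1, 1, 1]),
                            margin=100.0)
        assert vc.shape == (6, 6, 6)      # clamped; no invented padding

    def test_empty_mask_rejected(self):
        v = make_volume(np.zeros((4, 4, 4)), [1, 1, 1])
        lab = LabelMap(data=np.zeros((4, 4, 4), dtype=np.int64),
                       spacing=[1, 1, 1])
        with pytest.raises(ValueError):
            crop_breast(v, lab, margin=1.0)


class TestFcm:
    def test_two_point_masses(self):
        # with well-separated point masses the FCM fixed point sits at the
        # class means and memberships harden
        rng = np.random.default_rng(3)
        data = np.where(rng.uniform(size=(10, 10, 10)) < 0.4, 100.0, 200.0)
        v = make_volume(data, [1, 1, 1])
        mask = np.ones(v.shape, bool)
        res, labels = fcm_segment(v, mask, c=2)
        np.testing.assert_allclose(res.centroids, [100.0, 200.0], atol=1e-6)
        hard_ok = res.memberships.max(axis=1) >= 0.99
        assert hard_ok.all()
        assert set(np.unique(labels.data[mask])) == {Label.ADIPOSE,
                                                     Label.FIBROGLANDULAR}
        assert (labels.data[data == 100.0] == Label.ADIPOSE).all()

    def test_memberships_sum_to_one(self):
        rng = np.random.default_rng(4)
        v = make_volume(rng.normal(100, 30, size=(8, 8, 8)), [1, 1, 1])
        res, _ = fcm_segment(v, np.ones(v.shape, bool), c=3)
        np.testing.assert_allclose(res.memberships.sum(axis=1), 1.0,
                                   atol=1e-12)

    def test_objective_nonincreasing(self):
        rng = np.random.default_rng(5)
        v = make_volume(np.concatenate([rng.normal(0, 1, 300),
                                        rng.normal(10, 1, 300)])
                        .reshape(6, 10, 10), [1, 1, 1])
        res, _ = fcm_segment(v, np.ones(v.shape, bool), c=2)
        obj = np.array(res.objective)
        assert np.all(np.diff(obj) <= 1e-9 * obj[0])

    def test_voxel_on_centroid_gets_crisp_membership(self):
        # percentile initialisation puts the low centroid exactly on the
        # value 0, so the singularity rule must assign crisp membership
        data = np.array([0.0, 0.0, 0.0, 10.0, 20.0]).reshape(5, 1, 1)
        v = make_volume(data, [1, 1, 1])
        with np.testing.suppress_warnings() as sup:
            sup.filter(UserWarning)
            res, _ = fcm_segment(v, np.ones(v.shape, bool), c=2, max_iter=1)
        np.testing.assert_array_equal(res.memberships[0], [1.0, 0.0])

    def test_phantom_ct_recovers_true_labels(self, small_case):
        case = small_case
        mask = case.labels_supine.breast_mask()
        _, labels = fcm_segment(case.ct_supine, mask)
        truth = case.labels_supine.data.copy()
        truth[truth == Label.LESION] = Label.FIBROGLANDULAR
        inside = mask & (case.labels_supine.data != Label.LESION)
        agreement = (labels.data[inside] == truth[inside]).mean()
        assert agreement >= 0.99

    def test_invalid_inputs(self):
        v = make_volume(np.zeros((4, 4, 4)), [1, 1, 1])
        with pytest.raises(ValueError):
            fcm_segment(v, np.zeros(v.shape, bool))
        with pytest.raises(ValueError):
            fcm_segment(v, np.ones(v.shape, bool), c=1)


class TestVolumeDensity:
    def test_counting_example(self):
        lab = np.zeros((10, 10, 10), dtype=np.int64)
        lab.reshape(-1)[:1000] = Label.ADIPOSE
        lab.reshape(-1)[:270] = Label.FIBROGLANDULAR
        lm = LabelMap(data=lab, spacing=[1, 1, 1])
        vol, dens = breast_volume_and_density(lm)
        assert vol == pytest.approx(1.0)
        assert dens == pytest.approx(0.27)

    def test_all_gland_density_one(self):
        lab = np.full((4, 4, 4), int(Label.FIBROGLANDULAR))
        vol, dens = breast_volume_and_density(LabelMap(data=lab,
                                                       spacing=[2, 2, 2]))
        assert dens == 1.0
        assert vol == pytest.approx(64 * 8 / 1000.0)

    def test_lesion_counts_toward_volume_not_density(self):
        lab = np.zeros((10, 1, 1), dtype=np.int64)
        lab[:5, 0, 0] = Label.ADIPOSE
        lab[5:9, 0, 0] = Label.FIBROGLANDULAR
        lab[9, 0, 0] = Label.LESION
        _, dens = breast_volume_and_density(LabelMap(data=lab, spacing=[1, 1, 1]))
        assert dens == pytest.approx(0.4)

    def test_empty_breast_rejected(self):
        lab = LabelMap(data=np.zeros((3, 3, 3), dtype=np.int64),
                       spacing=[1, 1, 1])
        with pytest.raises(ValueError):
            breast_volume_and_density(lab)

    def test_phantom_density_matches_target(self, small_case):
        _, dens = breast_volume_and_density(small_case.labels_supine)
        assert abs(dens - small_case.truth.volumetric_density_target) <= 0.02
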