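"""Affine registration, interpolation primitives and composites."""

import numpy as np
import pytest

import phmribold as pb
from phmribold.registration import _FWHM_TO_SIGMA

from conftest import RED_SHAPE, RED_VS, center_mm


class TestAffineTransform:
    def test_params_matrix_round_trip(self):
        tr = pb.AffineTransform.from_params(
            (1.0, -2.0, 0.5), (0.1, -0.05, 0.2), (1.05, 0.95, 1.0),
            center=(5.0, 5.0, 5.0),
        )
        again = pb.AffineTransform.from_params(
            tr.translation, tr.rotation, tr.scale, center=tr.center
        )
        assert np.allclose(tr.matrix, again.matrix)

    def test_inverse_composes_to_identity(self):
        tr = pb.AffineTransform.from_params((1, 2, 3), (0.2, 0.1, -0.3), (1.1, 0.9, 1.2))
        assert np.allclose(tr.matrix @ tr.inverse_matrix, np.eye(4), atol=1e-10)
        pts = np.random.default_rng(0).uniform(-5, 5, (20, 3))
        assert np.allclose(tr.apply_inverse(tr.apply(pts)), pts, atol=1e-10)

    def test_json_round_trip(self):
        tr = pb.AffineTransform.from_params((1, 0, 0), (0, 0, 0.3), (1, 1, 1))
        back = pb.AffineTransform.from_json(tr.to_json())
        assert np.allclose(back.matrix, tr.matrix)


class TestSmoothGaussian:
    def test_zero_fwhm_identity(self):
        rng = np.random.default_rng(0)
        vol = rng.normal(size=(10, 10, 5))
        assert np.array_equal(pb.smooth_gaussian(vol, 0.0, (1, 1, 1)), vol)

    def test_mass_conserved(self):
        vol = np.zeros((40, 40, 20))
        vol[20, 20, 10] = 1.0
        out = pb.smooth_gaussian(vol, 2.0, (1, 1, 1))
        assert out.sum() == pytest.approx(1.0, rel=1e-6)

    def test_impulse_matches_closed_form(self):
        vol = np.zeros((41, 41, 21))
        vol[20, 20, 10] = 1.0
        fwhm, vs = 3.0, (1.0, 1.0, 1.0)
        out = pb.smooth_gaussian(vol, fwhm, vs)
        sigma = fwhm * _FWHM_TO_SIGMA
        x = np.arange(41) - 20.0
        g1 = np.exp(-(x**2) / (2 * sigma**2))
        g1 /= g1.sum()
        z = np.arange(21) - 10.0
        gz = np.exp(-(z**2) / (2 * sigma**2))
        gz /= gz.sum()
        expected = g1[:, None, None] * g1[None, :, None] * gz[None, None, :]
        assert np.allclose(out, expected, atol=1e-6)


class TestTrilinear:
    def test_voxel_center_exact(self):
        rng = np.random.default_rng(1)
        vol = rng.normal(size=(6, 7, 8))
        assert pb.trilinear_sample(vol, np.array([2.0, 3.0, 4.0])) == vol[2, 3, 4]

    def test_midpoint_average(self):
        vol = np.zeros((4, 4, 4))
        vol[1, 1, 1] = 0.0
        vol[2, 1, 1] = 10.0
        assert pb.trilinear_sample(vol, np.array([1.5, 1.0, 1.0])) == pytest.approx(5.0)

    def test_reproduces_trilinear_functions_exactly(self):
        # f(x,y,z) = x + 2y + 3z is reproduced exactly by trilinear weights
        idx = np.indices((8, 8, 8)).astype(float)
        vol = idx[0] + 2 * idx[1] + 3 * idx[2]
        rng = np.random.default_rng(2)
        pts = rng.uniform(0, 7, (200, 3))
        vals = pb.trilinear_sample(vol, pts)
        expected = pts[:, 0] + 2 * pts[:, 1] + 3 * pts[:, 2]
        assert np.allclose(vals, expected, atol=1e-12)

    def test_out_of_bounds_is_missing_not_zero(self):
        vol = np.ones((4, 4, 4))
        val = pb.trilinear_sample(vol, np.array([-0.6, 1.0, 1.0]))
        assert np.isnan(val)


class TestRegisterAffine:
    def test_self_registration_is_identity(self, template12):
        tr = pb.register_affine(template12, template12, voxel_size=RED_VS)
        assert np.allclose(tr.translation, 0, atol=0.01)
        assert np.allclose(tr.rotation, 0, atol=0.01)
        assert np.allclose(tr.scale, 1, atol=0.005)

    def test_known_transform_recovered(self, atlas12, anatomy12, template12):
        true = pb.AffineTransform.from_params(
            (2.0, -1.0, 0.5), (0.0873, 0.03, -0.05), (1.03, 0.98, 1.01),
            center=center_mm(RED_SHAPE, RED_VS),
        )
        subj = pb.simulate_bold(
            atlas12, true, [], noise_sd=0, drift_slope=0, seed=0, anatomy=anatomy12
        ).truth.anatomy
        est = pb.register_affine(subj, template12, voxel_size=RED_VS)
        # 5% of each true parameter magnitude
        assert np.allclose(est.translation, true.translation, atol=0.05 * 2.0)
        assert np.allclose(est.rotation, true.rotation, atol=0.05 * 0.0873)
        assert np.abs(np.array(est.scale) - true.scale).max() <= 0.05 * 0.03

    def test_recovery_with_additive_noise(self, atlas12, anatomy12, template12):
        true = pb.AffineTransform.from_params(
            (2.0, -1.0, 0.5), (0.0873, 0.03, -0.05), (1.03, 0.98, 1.01),
            center=center_mm(RED_SHAPE, RED_VS),
        )
        subj = pb.simulate_bold(
            atlas12, true, [], noise_sd=0, drift_slope=0, seed=0, anatomy=anatomy12
        ).truth.anatomy
        rng = np.random.default_rng(7)
        noisy = subj * (1.0 + 0.01 * rng.standard_normal(subj.shape))
        est = pb.register_affine(noisy, template12, voxel_size=RED_VS)
        assert np.allclose(est.translation, true.translation, atol=0.10 * 2.0)
        assert np.allclose(est.rotation, true.rotation, atol=0.10 * 0.0873)
        assert np.abs(np.array(est.scale) - true.scale).max() <= 0.10 * 0.03


class TestComposite:
    def _amap(self, pos, neg=None, vs=(1.0, 1.0, 1.0)):
        neg = np.zeros_like(pos) if neg is None else neg
        return pb.ActivationMap(positive=pos, negative=neg, voxel_size=vs)

    def _atlas_like(self, shape, vs=(1.0, 1.0, 1.0)):
        labels = np.ones(shape, dtype=np.int32)
        return pb.LabeledAtlas(labels=labels, names={1: "all"}, voxel_size=vs)

    def test_single_subject_identity_equals_map(self):
        rng = np.random.default_rng(0)
        pos = np.clip(rng.normal(3, 1, (6, 6, 4)), 0, None)
        comp = pb.build_composite(
            [self._amap(pos)], [pb.AffineTransform.identity()],
            self._atlas_like((6, 6, 4)),
        )
        assert np.allclose(comp.positive, pos, atol=1e-12)

    def test_zero_inclusive_averaging(self):
        m = np.zeros((5, 5, 3))
        m[2, 2, 1] = 6.0
        maps = [self._amap(m.copy()), self._amap(np.zeros_like(m))]
        comp = pb.build_composite(
            maps, [pb.AffineTransform.identity()] * 2, self._atlas_like((5, 5, 3))
        )
        # second subject contributes a zero at the peak: mean is m/2
        assert comp.positive[2, 2, 1] == pytest.approx(3.0)
        comp_nz = pb.build_composite(
            maps, [pb.AffineTransform.identity()] * 2, self._atlas_like((5, 5, 3)),
            include_zeros=False,
        )
        assert comp_nz.positive[2, 2, 1] == pytest.approx(6.0)

    def test_n_identical_subjects_equal_one(self):
        rng = np.random.default_rng(5)
        pos = np.clip(rng.normal(2, 1, (6, 6, 4)), 0, None)
        maps = [self._amap(pos.copy()) for _ in range(4)]
        comp = pb.build_composite(
            maps, [pb.AffineTransform.identity()] * 4, self._atlas_like((6, 6, 4))
        )
        assert np.allclose(comp.positive, pos, atol=1e-12)

    def test_missing_transform_reported(self):
        with pytest.raises(ValueError, match="lack a transform"):
            pb.build_composite(
                [self._amap(np.zeros((4, 4, 2)))], [], self._atlas_like((4, 4, 2))
            )

    def test_translated_subjects_peak_at_atlas_centroid(self, atlas12, anatomy12):
        """Subjects displaced by known translations: the composite peak
        must land on the atlas-space effect centroid within one voxel."""
        rid = 3
        maps, transforms = [], []
        for k, t in enumerate([(1.5, 0, 0), (-1.5, 0.75, 0), (0, -1.5, 0.75)]):
            tr = pb.AffineTransform.from_params(t, (0, 0, 0), (1, 1, 1))
            s = pb.simulate_bold(
                atlas12, tr, [pb.RegionEffect(rid, +5.0)], noise_sd=0,
                drift_slope=0, seed=k, anatomy=anatomy12,
            )
            pos = np.where(s.truth.positive_mask, 5.0, 0.0)
            maps.append(self._amap(pos, vs=RED_VS))
            transforms.append(tr)
        comp = pb.build_composite(maps, transforms, atlas12)
        region = atlas12.labels == rid
        centroid_true = np.argwhere(region).mean(axis=0)
        w = comp.positive
        centroid_comp = np.argwhere(w > 0.5 * w.max()).mean(axis=0)
        assert np.all(np.abs(centroid_comp - centroid_true) <= 1.0)

    def test_warp_round_trip_error_small(self, template12):
        tr = pb.AffineTransform.from_params(
            (1.0, -0.5, 0.3), (0.05, -0.02, 0.04), (1.02, 0.99, 1.01),
            center=center_mm(RED_SHAPE, RED_VS),
        )
        warped = pb.resample_to_grid(
            template12, tr, RED_SHAPE, RED_VS, RED_VS, fill=np.nan
        )
        back = pb.resample_to_grid(
            warped, tr.inverse(), RED_SHAPE, RED_VS, RED_VS, fill=np.nan
        )
        ok = np.isfinite(back)
        err = np.abs(back[ok] - template12[ok]).mean()
        assert err < 0.02 * (template12.max() - template12.min())
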