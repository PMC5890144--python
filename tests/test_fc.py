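"""FC pipeline: nuisance regression, smoothing, QC, decomposition,
template matching, dual regression and inter-network connectivity."""

import numpy as np
import pytest

from tvanet.fc import (dual_regression, fisher_z, group_decompose,
                       internetwork_fc, match_templates, motion_qc,
                       nuisance_regress, smooth, tsnr, QCThresholds)
from tvanet.simulate import make_network_templates


def _img(rng, shape=(8, 8, 4), T=50):
    return rng.standard_normal(shape + (T,))


class TestNuisanceRegress:
    def test_intercept_only_demeans(self):
        rng = np.random.default_rng(0)
        img = _img(rng)
        out = nuisance_regress(img, None)
        np.testing.assert_allclose(out.mean(axis=3), 0.0, atol=1e-10)
        np.testing.assert_allclose(out, img - img.mean(3, keepdims=True),
                                   atol=1e-10)

    def test_confound_column_removed_exactly(self):
        rng = np.random.default_rng(1)
        conf = rng.standard_normal((40, 2))
        img = np.tile(conf[:, 0], (4, 4, 2, 1))
        out = nuisance_regress(img, conf)
        assert np.abs(out).max() < 1e-8

    def test_residuals_orthogonal_to_confounds(self):
        rng = np.random.default_rng(2)
        img = _img(rng, T=60)
        conf = rng.standard_normal((60, 4))
        out = nuisance_regress(img, conf)
        flat = out.reshape(-1, 60)
        cz = (conf - conf.mean(0)) / conf.std(0)
        dots = flat @ cz / 60
        assert np.abs(dots).max() < 1e-8

    def test_known_drift_removed(self):
        rng = np.random.default_rng(3)
        T = 80
        drift = np.linspace(-1, 1, T)
        img = _img(rng, T=T) + 5 * drift
        out = nuisance_regress(img, drift[:, None])
        flat = out.reshape(-1, T)
        r = (flat - flat.mean(1, keepdims=True)) @ (drift - drift.mean())
        r /= (flat.std(1) * T * drift.std() + 1e-30)
        assert np.abs(r).max() < 0.01

    def test_rank_deficiency_names_columns(self):
        rng = np.random.default_rng(4)
        a = rng.standard_normal(30)
        conf = np.column_stack([a, 2 * a])
        with pytest.raises(ValueError, match="offending columns"):
            nuisance_regress(_img(rng, T=30), conf)


class TestSmooth:
    def test_fwhm_zero_identity(self):
        rng = np.random.default_rng(5)
        img = _img(rng)
        assert smooth(img, 0.0, 2.0) is img

    def test_delta_peak_matches_kernel_constant(self):
        # FWHM 4 mm at 2 mm voxels -> sigma = 0.8493 voxels; the smoothed
        # delta's peak equals the 3D Gaussian normalisation constant
        img = np.zeros((21, 21, 21, 1))
        img[10, 10, 10, 0] = 1.0
        out = smooth(img, 4.0, 2.0)
        sigma = 4.0 / (2 * np.sqrt(2 * np.log(2))) / 2.0
        assert sigma == pytest.approx(0.8493, abs=1e-4)
        expect = (1 / (np.sqrt(2 * np.pi) * sigma)) ** 3
        assert out[10, 10, 10, 0] == pytest.approx(expect, rel=1e-3)

    def test_constant_image_unchanged_and_sum_conserved(self):
        img = np.full((10, 10, 6, 3), 7.0)
        out = smooth(img, 4.0, 2.0)
        np.testing.assert_allclose(out, img, rtol=1e-12)
        rng = np.random.default_rng(6)
        img = _img(rng)
        out = smooth(img, 6.0, 2.0)
        assert out.sum() == pytest.approx(img.sum(), rel=1e-6)


class TestMotionQC:
    def test_all_zero(self):
        rec = motion_qc(np.zeros((50, 6)))
        assert not rec.excluded
        assert rec.cumulative_translation_mm == 0.0
        assert rec.mean_rotation_deg == 0.0

    def test_single_jump_excluded(self):
        m = np.zeros((50, 6))
        m[25:, 0] = 4.0  # 4 mm jump
        rec = motion_qc(m)
        assert rec.cumulative_translation_mm == pytest.approx(4.0)
        assert rec.excluded and "cumulative_translation" in rec.reasons

    def test_mean_point_to_point_rule(self):
        m = np.zeros((50, 6))
        m[:, 1] = np.arange(50) * 0.2  # 0.2 mm per volume
        rec = motion_qc(m)
        assert rec.mean_translation_mm == pytest.approx(0.2)
        assert rec.excluded and "mean_translation" in rec.reasons

    def test_wrong_columns_rejected(self):
        with pytest.raises(ValueError, match="6 columns"):
            motion_qc(np.zeros((50, 5)))


class TestTSNR:
    def test_mean_over_sd(self):
        rng = np.random.default_rng(7)
        img = 10.0 + rng.standard_normal((6, 6, 3, 4000))
        scalar, tmap, nex = tsnr(img)
        assert scalar == pytest.approx(10.0, rel=0.05)
        assert nex == 0

    def test_scale_property(self):
        rng = np.random.default_rng(8)
        img = 10.0 + rng.standard_normal((5, 5, 2, 200))
        s1, _, _ = tsnr(img)
        s2, _, _ = tsnr(img + img.mean(3, keepdims=True))
        assert s2 == pytest.approx(2 * s1, rel=1e-6)

    def test_zero_variance_excluded(self):
        rng = np.random.default_rng(9)
        img = 5.0 + rng.standard_normal((4, 4, 2, 30))
        img[0, 0, 0, :] = 3.0
        _, _, nex = tsnr(img)
        assert nex == 1


class TestGroupDecompose:
    def _scene(self, seed=10, noise=0.0):
        rng = np.random.default_rng(seed)
        shape, T, G = (14, 14, 7), 60, 3
        maps = make_network_templates(shape, G, seed=seed,
                                      max_pairwise_corr=0.25)
        imgs = []
        for _ in range(4):
            tc = rng.standard_normal((T, G))
            data = maps.reshape(G, -1).T @ tc.T
            data += noise * rng.standard_normal(data.shape)
            imgs.append(data.reshape(shape + (T,)))
        return maps, imgs

    def test_recovers_planted_maps(self):
        maps, imgs = self._scene(noise=0.05)
        comps = group_decompose(imgs, n_components=3, seed=1)
        matches = match_templates(comps, maps)
        assert all(abs(m["r"]) > 0.95 for m in matches)

    def test_subject_order_irrelevant_for_subspace(self):
        maps, imgs = self._scene(noise=0.02)
        a = group_decompose(imgs, n_components=3, seed=2)
        b = group_decompose(imgs[::-1], n_components=3, seed=2)
        # compare spanned spatial subspaces via principal angles
        qa, _ = np.linalg.qr(a.maps.reshape(3, -1).T)
        qb, _ = np.linalg.qr(b.maps.reshape(3, -1).T)
        s = np.linalg.svd(qa.T @ qb, compute_uv=False)
        assert np.all(s > 1 - 1e-6)

    def test_deterministic(self):
        maps, imgs = self._scene(noise=0.05)
        a = group_decompose(imgs, n_components=3, seed=3)
        b = group_decompose(imgs, n_components=3, seed=3)
        np.testing.assert_array_equal(a.maps, b.maps)

    def test_positive_skew_convention(self):
        from scipy.stats import skew
        maps, imgs = self._scene(noise=0.05)
        comps = group_decompose(imgs, n_components=3, seed=4)
        assert np.all(skew(comps.maps.reshape(3, -1), axis=1) >= 0)


class TestMatchTemplates:
    def test_identical_map_r_one(self):
        maps = make_network_templates((12, 12, 6), 3, seed=20)
        matches = match_templates(maps, maps)
        assert all(m["template"] == m["component"] for m in matches)
        assert all(m["r"] == pytest.approx(1.0) for m in matches)

    def test_independent_maps_near_zero(self):
        rng = np.random.default_rng(21)
        a = rng.standard_normal((3, 12, 12, 6))
        b = rng.standard_normal((3, 12, 12, 6))
        matches = match_templates(a, b)
        assert all(abs(m["r"]) < 0.15 for m in matches)

    def test_grid_mismatch_rejected(self):
        a = np.zeros((2, 8, 8, 4))
        b = np.zeros((2, 10, 10, 4))
        with pytest.raises(ValueError, match="grid mismatch"):
            match_templates(a, b)


class TestDualRegression:
    def test_exact_recovery_noise_free(self):
        rng = np.random.default_rng(22)
        maps = make_network_templates((12, 12, 6), 2, seed=23)
        tc = rng.standard_normal((50, 2))
        data = (maps.reshape(2, -1).T @ tc.T).reshape(12, 12, 6, 50)
        dr = dual_regression(data, maps)
        for g in range(2):
            r = np.corrcoef(dr.timecourses[:, g], tc[:, g])[0, 1]
            assert abs(r) > 0.9999
        # stage-2 coefficients reproduce the map itself (exact regression)
        np.testing.assert_allclose(
            dr.betas[0], maps[0] * tc[:, 0].std(ddof=1), atol=1e-8)

    def test_joint_regression_controls_other_components(self):
        rng = np.random.default_rng(24)
        maps = make_network_templates((12, 12, 6), 2, seed=25)
        tc = rng.standard_normal((60, 2))
        tc[:, 1] -= tc[:, 0] * (tc[:, 0] @ tc[:, 1]) / (tc[:, 0] @ tc[:, 0])
        base = (maps[0].reshape(-1, 1) @ tc[:, :1].T)
        both = base + maps[1].reshape(-1, 1) @ tc[:, 1:].T
        dr1 = dual_regression(base.reshape(12, 12, 6, 60), maps)
        dr2 = dual_regression(both.reshape(12, 12, 6, 60), maps)
        np.testing.assert_allclose(dr1.betas[0], dr2.betas[0], atol=1e-6)

    def test_planted_gain_proportionality(self):
        # stage-2 betas proportional to the planted gains, noise-free
        rng = np.random.default_rng(26)
        maps = make_network_templates((12, 12, 6), 3, seed=27)
        gains = np.array([0.5, 1.0, 2.0])
        tc = rng.standard_normal((80, 3))
        data = ((maps.reshape(3, -1).T * gains) @ tc.T).reshape(12, 12, 6, 80)
        dr = dual_regression(data, maps)
        peak = [dr.betas[g][tuple(np.unravel_index(
            np.argmax(maps[g]), maps[g].shape))] for g in range(3)]
        fitted = np.polyfit(gains, peak, 1)
        resid = np.polyval(fitted, gains) - peak
        ss = 1 - resid @ resid / np.var(peak) / 3
        assert ss > 0.99

    def test_collinear_maps_rejected(self):
        maps = np.zeros((2, 8, 8, 4))
        maps[0, 2:5, 2:5, 1] = 1.0
        maps[1] = maps[0] * 2
        with pytest.raises(ValueError, match="collinear"):
            dual_regression(np.zeros((8, 8, 4, 30)), maps)


class TestInternetworkFC:
    def test_identical_pair_capped(self):
        rng = np.random.default_rng(28)
        a = rng.standard_normal(100)
        tc = np.column_stack([a, a, rng.standard_normal(100)])
        z = internetwork_fc(tc)
        assert np.isfinite(z[0, 1])
        assert z[0, 1] == pytest.approx(np.arctanh(1 - 1e-15))

    def test_independent_noise_near_zero(self):
        rng = np.random.default_rng(29)
        T = 250
        tc = rng.standard_normal((T, 2))
        z = internetwork_fc(tc)
        assert abs(z[0, 1]) < 3 / np.sqrt(T - 3)

    def test_odd_symmetry(self):
        r = np.array(0.37)
        assert fisher_z(-r) == pytest.approx(-fisher_z(r))

    def test_constant_rejected(self):
        tc = np.ones((50, 2))
        with pytest.raises(ValueError, match="constant"):
            internetwork_fc(tc)

    def test_diagonal_nan(self):
        rng = np.random.default_rng(30)
        z = internetwork_fc(rng.standard_normal((60, 4)))
        assert np.all(np.isnan(np.diag(z)))
        np.testing.assert_allclose(z, z.T, equal_nan=True)


class TestPipelineOrder:
    def test_regress_and_smooth_commute_for_fixed_confounds(self):
        # nuisance regression projects along time, smoothing convolves along
        # space: for a fixed confound matrix the two linear operators act on
        # orthogonal axes and commute.  The pipeline still fixes the order
        # (regress, then smooth) because its global-signal confound is
        # derived from the unsmoothed data.
        rng = np.random.default_rng(40)
        img = _img(rng, shape=(10, 10, 5), T=40) + 3.0
        conf = rng.standard_normal((40, 3))
        a = smooth(nuisance_regress(img, conf), 6.0, 2.0)
        b = nuisance_regress(smooth(img, 6.0, 2.0), conf)
        np.testing.assert_allclose(a, b, atol=1e-8)
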