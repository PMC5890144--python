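"""Group-level statistics: splits, t-tests, voxelwise GLM, clusters,
inter-network tests, eigenvariates and partial correlation."""

import numpy as np
import pytest
from scipy import stats

from tvanet import reference
from tvanet.group import (GroupGLM, bonferroni_networks, group_ttest_summary,
                          internetwork_group_test, intra_network_scalar,
                          median_split, partial_correlation)


class TestMedianSplit:
    def test_sixteen_fifteen_at_31(self):
        rng = np.random.default_rng(0)
        labels = median_split(rng.standard_normal(31))
        assert (labels == "high").sum() == 16
        assert (labels == "low").sum() == 15

    def test_higher_better(self):
        labels = median_split(np.arange(1, 11), higher_is_better=True)
        assert list(labels[5:]) == ["high"] * 5
        assert list(labels[:5]) == ["low"] * 5

    def test_lower_better_for_top_down_control(self):
        alpha = np.array([0.2, 0.8, 0.3, 0.9, 0.5, 0.4, 0.7])
        labels = median_split(alpha, higher_is_better=False)
        assert labels[0] == "high" and labels[3] == "low"
        # the "high performance" group has the lower alpha values
        assert alpha[labels == "high"].mean() < alpha[labels == "low"].mean()

    def test_all_tied_rejected(self):
        with pytest.raises(ValueError, match="tied"):
            median_split(np.ones(10))

    def test_groups_differ_only_on_split_parameter(self):
        # the split parameter separates; an independent parameter does not
        rng = np.random.default_rng(1)
        rejections = 0
        for _ in range(100):
            c = rng.normal(25.89, 7.34, 31)
            other = rng.normal(0.52, 0.21, 31)
            labels = median_split(c)
            hi, lo = c[labels == "high"], c[labels == "low"]
            t, p = stats.ttest_ind(hi, lo)
            assert p < 1e-4
            _, p2 = stats.ttest_ind(other[labels == "high"],
                                    other[labels == "low"])
            rejections += p2 < 0.05
        assert rejections <= 12  # ~nominal 5% for the untouched parameter


class TestSummaryTTests:
    def test_welch_matches_scipy(self):
        # independent route: scipy's summary-statistics t-test
        res = group_ttest_summary(30.76, 7.05, 16, 20.70, 2.45, 15, "welch")
        t_sp, p_sp = stats.ttest_ind_from_stats(30.76, 7.05, 16,
                                                20.70, 2.45, 15,
                                                equal_var=False)
        assert res.t == pytest.approx(t_sp, rel=1e-12)
        assert res.p == pytest.approx(p_sp, rel=1e-9)

    def test_pooled_matches_scipy(self):
        res = group_ttest_summary(0.34, 0.12, 16, 0.71, 0.10, 15, "pooled")
        t_sp, _ = stats.ttest_ind_from_stats(0.34, 0.12, 16, 0.71, 0.10, 15,
                                             equal_var=True)
        assert res.t == pytest.approx(t_sp, rel=1e-12)
        assert res.df == 29

    def test_identical_groups_zero(self):
        res = group_ttest_summary(1.0, 0.5, 10, 1.0, 0.5, 10, "welch")
        assert res.t == 0.0

    def test_welch_df_values_from_reference_groups(self):
        c = reference.GROUPS["C"]
        res = group_ttest_summary(*c["high"], *c["low"], "welch")
        assert res.df == pytest.approx(18.8, abs=0.1)
        k = reference.GROUPS["K"]
        res_k = group_ttest_summary(*k["high"], *k["low"], "welch")
        assert round(res_k.df) == 17


class TestVoxelwiseGLM:
    def test_reduces_to_two_sample_t(self):
        rng = np.random.default_rng(2)
        zmaps = rng.standard_normal((20, 6, 6, 3))
        labels = np.array(["high"] * 10 + ["low"] * 10)
        res = GroupGLM(zmaps, labels).fit()
        flat = zmaps.reshape(20, -1)
        t_ref, _ = stats.ttest_ind(flat[:10], flat[10:], equal_var=True)
        np.testing.assert_allclose(res.tmap.ravel(), t_ref, atol=1e-10)
        assert res.df == 18

    def test_df_24_with_seven_columns_at_31(self):
        rng = np.random.default_rng(3)
        zmaps = rng.standard_normal((31, 5, 5, 2))
        labels = median_split(rng.standard_normal(31))
        cov = rng.standard_normal((31, 5))
        res = GroupGLM(zmaps, labels, cov).fit()
        assert res.df == 24

    def test_planted_effect_detected(self):
        # a d=1.2 group shift in a block of voxels exceeds the height
        # threshold at the peak in nearly all replicates
        rng = np.random.default_rng(4)
        hits = 0
        n_rep = 40
        for _ in range(n_rep):
            zmaps = rng.standard_normal((31, 8, 8, 4))
            labels = median_split(rng.standard_normal(31))
            zmaps[labels == "high", 2:5, 2:5, 1:3] += 1.2
            res = GroupGLM(zmaps, labels).fit()
            thr = stats.t.isf(0.001, res.df)
            hits += res.tmap[2:5, 2:5, 1:3].max() > thr
        assert hits / n_rep >= 0.9

    def test_rank_deficiency_rejected(self):
        zmaps = np.random.default_rng(5).standard_normal((10, 4, 4, 2))
        labels = np.array(["high"] * 5 + ["low"] * 5)
        cov = np.column_stack([labels == "high"]).astype(float)
        with pytest.raises(ValueError, match="rank deficient"):
            GroupGLM(zmaps, labels, cov).fit()


class TestClusterInference:
    def test_all_zero_map_no_clusters(self):
        zmaps = np.zeros((12, 6, 6, 3))
        labels = np.array(["high"] * 6 + ["low"] * 6)
        res = GroupGLM(zmaps, labels).fit()
        np.testing.assert_array_equal(res.tmap, 0.0)
        clu = res.cluster_inference(n_perm=120, seed=1)
        assert clu.sizes == [] and not clu.any_significant

    def test_planted_blob_single_surviving_cluster(self):
        rng = np.random.default_rng(7)
        zmaps = rng.standard_normal((31, 10, 10, 5))
        labels = median_split(rng.standard_normal(31))
        zmaps[labels == "high", 3:7, 3:7, 1:4] += 2.5
        res = GroupGLM(zmaps, labels).fit()
        clu = res.cluster_inference(n_perm=300, seed=2)
        sig = [i for i, p in enumerate(clu.corrected_ps) if p < 0.05]
        assert len(sig) == 1
        peak = clu.peak_voxels[sig[0]]
        assert (3 <= peak[0] < 7) and (3 <= peak[1] < 7) and (1 <= peak[2] < 4)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(8)
        zmaps = rng.standard_normal((20, 8, 8, 4))
        labels = np.array(["high", "low"] * 10)
        res = GroupGLM(zmaps, labels).fit()
        a = res.cluster_inference(n_perm=150, seed=3, height_p=0.05)
        b = res.cluster_inference(n_perm=150, seed=3, height_p=0.05)
        assert a.corrected_ps == b.corrected_ps

    def test_small_n_perm_warns(self):
        rng = np.random.default_rng(9)
        zmaps = rng.standard_normal((12, 5, 5, 3))
        labels = np.array(["high"] * 6 + ["low"] * 6)
        res = GroupGLM(zmaps, labels).fit()
        with pytest.warns(UserWarning, match="n_perm"):
            res.cluster_inference(n_perm=50, seed=4)


class TestBonferroni:
    def test_threshold_and_decisions(self):
        survives, thr = bonferroni_networks(0.001, 6)
        assert thr == 0.0083 and survives
        survives, _ = bonferroni_networks(0.038, 6)
        assert not survives


class TestInternetworkGroupTest:
    def test_equal_means_half(self):
        hi = np.linspace(-1, 1, 16) + 0.3
        lo = np.linspace(-0.8, 0.8, 15) + 0.3
        lo = lo - lo.mean() + hi.mean()  # exactly equal group means
        z = np.concatenate([hi, lo])
        labels = np.array(["high"] * 16 + ["low"] * 15)
        res = internetwork_group_test(z, labels)
        assert res.df == 29
        assert res.t == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(0.5, abs=1e-12)

    def test_one_tailed_direction(self):
        labels = np.array(["high"] * 16 + ["low"] * 15)
        z = np.concatenate([np.random.default_rng(11).normal(0.4, 0.1, 16),
                            np.random.default_rng(12).normal(0.1, 0.1, 15)])
        res = internetwork_group_test(z, labels, tail="high>low")
        assert res.p < 0.01
        res_rev = internetwork_group_test(z, labels, tail="low>high")
        assert res_rev.p > 0.99


class TestIntraNetworkScalar:
    def test_uniform_mean(self):
        zmaps = np.full((5, 4, 4, 2), 3.3)
        mask = np.zeros((4, 4, 2), bool)
        mask[1:3, 1:3, :] = True
        out = intra_network_scalar(zmaps, mask, "mean")
        np.testing.assert_allclose(out, 3.3)

    def test_eigenvariate_sign_and_rank_one(self):
        rng = np.random.default_rng(13)
        scores = rng.normal(1.0, 0.5, 12)
        profile = np.abs(rng.standard_normal(30))
        sub = np.outer(scores, profile)
        zmaps = sub.reshape(12, 5, 6)
        mask = np.ones((5, 6), bool)
        ev = intra_network_scalar(zmaps, mask, "eigenvariate")
        means = intra_network_scalar(zmaps, mask, "mean")
        assert np.corrcoef(ev, means)[0, 1] > 0.999
        assert abs(np.corrcoef(ev, scores)[0, 1]) > 0.9999

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            intra_network_scalar(np.ones((3, 2, 2)), np.zeros((2, 2), bool))


class TestPartialCorrelation:
    def test_uncorrelated_control_preserves_r(self):
        rng = np.random.default_rng(14)
        n = 4000
        x = rng.standard_normal(n)
        y = 0.5 * x + rng.standard_normal(n)
        ctrl = rng.standard_normal(n)
        r_partial, _ = partial_correlation(x, y, ctrl)
        r_simple = np.corrcoef(x, y)[0, 1]
        assert r_partial == pytest.approx(r_simple, abs=0.03)

    def test_y_equals_control_zero(self):
        rng = np.random.default_rng(15)
        x = rng.standard_normal(200)
        ctrl = rng.standard_normal(200)
        r, p = partial_correlation(x, ctrl, ctrl)
        assert r == 0.0 and p == 1.0

    def test_known_trivariate_partial(self):
        # construct (x, y, c) with known partial correlation 0.4 given c
        rng = np.random.default_rng(16)
        n = 1000
        c = rng.standard_normal(n)
        rho = 0.4
        e1 = rng.standard_normal(n)
        e2 = rho * e1 + np.sqrt(1 - rho**2) * rng.standard_normal(n)
        x, y = 0.8 * c + e1, -0.6 * c + e2
        r, p = partial_correlation(x, y, c)
        se = 1 / np.sqrt(n - 3)
        assert abs(np.arctanh(r) - np.arctanh(rho)) < 3 * se
        assert p < 1e-10

    def test_matches_pingouin_oracle(self):
        # cross-check against an independent implementation
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd
        rng = np.random.default_rng(17)
        df = pd.DataFrame(rng.standard_normal((60, 3)), columns=list("xyc"))
        df["y"] += 0.5 * df["x"] + 0.3 * df["c"]
        r, p = partial_correlation(df["x"], df["y"], df["c"])
        ref = pingouin.partial_corr(df, x="x", y="y", covar="c")
        pcol = "p_val" if "p_val" in ref.columns else "p-val"
        assert r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-9)
        assert p == pytest.approx(float(ref[pcol].iloc[0]), rel=1e-6)

    def test_constant_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            partial_correlation(np.ones(50), np.arange(50.0),
                                np.random.default_rng(18).standard_normal(50))


class TestNullCalibration:
    def test_null_tmap_distribution_matches_student_t(self):
        # end-to-end null: voxelwise t-statistics from the 7-column design
        # at n=31 follow Student t with 24 df
        rng = np.random.default_rng(20)
        tvals = []
        for _ in range(6):
            zmaps = rng.standard_normal((31, 12, 12, 6))
            labels = median_split(rng.standard_normal(31))
            cov = rng.standard_normal((31, 5))
            res = GroupGLM(zmaps, labels, cov).fit()
            assert res.df == 24
            tvals.append(res.tmap.ravel())
        t = np.concatenate(tvals)
        stat = stats.kstest(t, stats.t(24).cdf)
        assert stat.pvalue > 0.01
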