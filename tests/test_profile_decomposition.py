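"""Correlation-distance k-means and the two-Gaussian decomposition."""

import numpy as np
import pytest
from scipy.optimize import least_squares
from sklearn.metrics import adjusted_rand_score

from bivalentscope.profile_decomposition import (
    BimodalFit,
    _model,
    cluster_profiles,
    cluster_stability,
    evaluate_bimodal,
    fit_two_gaussians,
)
from bivalentscope.profile_engine import MetaProfile, ProfileMatrix


def make_matrix(values, bin_width=50):
    values = np.asarray(values, dtype=float)
    n, b = values.shape
    axis = (np.arange(b) - b / 2) * bin_width + bin_width / 2
    return ProfileMatrix(
        [f"g{i:03d}" for i in range(n)], axis, values, "tss", b * bin_width // 2, bin_width
    )


def two_shape_matrix(rng, n=100, bins=80, noise=0.05):
    """Planted partition: half narrow TSS-centered, half broad shifted."""
    x = np.linspace(-2000, 2000, bins)
    shapes = [
        np.exp(-(x**2) / (2 * 150**2)),
        np.exp(-((x - 455) ** 2) / (2 * 400**2)),
    ]
    truth = np.array([i % 2 for i in range(n)])
    vals = np.array([shapes[t] for t in truth])
    vals = np.clip(vals + rng.normal(0, noise, vals.shape), 0, None)
    return make_matrix(vals), truth


class TestClusterProfiles:
    def test_identical_rows_single_cluster(self):
        m = make_matrix(np.tile([0.0, 1.0, 3.0, 1.0, 0.1], (8, 1)))
        res = cluster_profiles(m, k=1, seed=0)
        assert set(res.assignment.values()) == {0}
        assert res.within_cluster_mean_corr == pytest.approx(1.0)

    def test_planted_partition_recovered(self):
        rng = np.random.default_rng(0)
        m, truth = two_shape_matrix(rng)
        res = cluster_profiles(m, k=2, seed=3)
        labels = res.labels(m.gene_ids)
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_objective_non_increasing(self):
        rng = np.random.default_rng(1)
        m = make_matrix(rng.random((60, 30)))
        res = cluster_profiles(m, k=3, seed=5)
        diffs = np.diff(res.objective_history)
        assert np.all(diffs <= 1e-10)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(2)
        m = make_matrix(rng.random((40, 20)))
        r1 = cluster_profiles(m, k=2, seed=9)
        r2 = cluster_profiles(m, k=2, seed=9)
        assert r1.assignment == r2.assignment
        np.testing.assert_array_equal(r1.centroids, r2.centroids)

    def test_zero_variance_rows_excluded(self):
        rng = np.random.default_rng(3)
        vals = rng.random((10, 15))
        vals[4] = 0.7  # flat row
        m = make_matrix(vals)
        res = cluster_profiles(m, k=2, seed=0)
        assert res.excluded == ["g004"]
        assert "g004" not in res.assignment

    def test_too_few_rows_rejected(self):
        m = make_matrix(np.random.default_rng(4).random((3, 10)))
        with pytest.raises(ValueError):
            cluster_profiles(m, k=5, seed=0)

    def test_row_scaling_does_not_change_assignment(self):
        # Pearson distance is invariant to per-row affine rescaling
        rng = np.random.default_rng(5)
        m, _ = two_shape_matrix(rng, n=40)
        scaled = make_matrix(m.values * rng.uniform(0.5, 5.0, (40, 1)) + 0.3)
        r1 = cluster_profiles(m, k=2, seed=1)
        r2 = cluster_profiles(scaled, k=2, seed=1)
        l1 = r1.labels(m.gene_ids)
        l2 = r2.labels(m.gene_ids)
        assert adjusted_rand_score(l1, l2) == 1.0


class TestClusterStability:
    def test_separated_data_fully_stable(self):
        rng = np.random.default_rng(6)
        m, _ = two_shape_matrix(rng, n=60)
        rep = cluster_stability(m, k=2, n_realizations=8, base_seed=0)
        assert rep.mean_ari == pytest.approx(1.0)
        assert np.all(np.diag(rep.ari_matrix) == 1.0)

    def test_pure_noise_unstable(self):
        rng = np.random.default_rng(7)
        m = make_matrix(rng.random((80, 40)))
        rep = cluster_stability(m, k=2, n_realizations=10, base_seed=0)
        assert rep.mean_ari < 0.2

    def test_ari_matches_hand_formula(self):
        # partitions of 6 items: [0,0,0,1,1,1] vs [0,0,0,1,1,2]
        # contingency pairs: 3 + 1 = 4; sum_a C(3,2)*2 = 6; sum_b = 3+1 = 4
        # expected = 6*4/15 = 1.6; max = 5 -> ARI = (4-1.6)/(5-1.6) = 12/17
        assert adjusted_rand_score([0, 0, 0, 1, 1, 1], [0, 0, 0, 1, 1, 2]) == pytest.approx(12 / 17)

    def test_too_few_realizations_rejected(self):
        m = make_matrix(np.random.default_rng(8).random((10, 10)))
        with pytest.raises(ValueError):
            cluster_stability(m, k=2, n_realizations=1)


TRUTH = dict(mu1=-40.0, s1=80.0, mu2=450.0, s2=400.0, w=0.4, a=1.0)


def truth_profile(bins=200, flank=5000, **over):
    p = {**TRUTH, **over}
    axis = np.linspace(-flank, flank, bins)
    y = _model(axis, p["mu1"], p["s1"], p["mu2"], p["s2"], p["w"], p["a"])
    return MetaProfile(axis, y, 100), p


class TestFitTwoGaussians:
    def test_noise_free_recovery(self):
        mp, p = truth_profile()
        fit = fit_two_gaussians(mp)
        assert abs(fit.mu1 - p["mu1"]) < 1.0
        assert abs(fit.mu2 - p["mu2"]) < 1.0
        assert abs(fit.sigma1 - p["s1"]) / p["s1"] < 1e-3
        assert abs(fit.sigma2 - p["s2"]) / p["s2"] < 1e-3
        assert abs(fit.w - p["w"]) / p["w"] < 1e-3
        assert abs(fit.amplitude - p["a"]) < 1e-3
        assert fit.converged

    def test_single_gaussian_data_nested_bound(self):
        mp, p = truth_profile(w=0.999)  # essentially one component at mu1
        fit = fit_two_gaussians(mp)
        # single-Gaussian oracle fit
        axis, y = mp.axis, mp.values

        def res(theta):
            mu, s, a = theta
            return a * np.exp(-((axis - mu) ** 2) / (2 * s**2)) - y

        single = least_squares(res, [0.0, 500.0, y.max()],
                               bounds=([-5000, 10, 0], [5000, 10000, np.inf]))
        rss_single = 2 * single.cost
        assert fit.rss <= rss_single + 1e-12
        minor = min(fit.w, 1 - fit.w)
        assert minor < 0.05 or abs(fit.mu1 - fit.mu2) < 50

    def test_identically_zero_rejected(self):
        axis = np.linspace(-1000, 1000, 50)
        with pytest.raises(ValueError):
            fit_two_gaussians(MetaProfile(axis, np.zeros(50), 1))

    def test_too_few_bins_rejected(self):
        axis = np.linspace(-100, 100, 8)
        with pytest.raises(ValueError):
            fit_two_gaussians(MetaProfile(axis, np.ones(8), 1))

    def test_mu_ordering_enforced(self):
        mp, _ = truth_profile()
        fit = fit_two_gaussians(mp)
        assert fit.mu1 <= fit.mu2

    def test_rescaling_only_scales_amplitude(self):
        rng = np.random.default_rng(10)
        mp, _ = truth_profile()
        noisy = np.clip(mp.values + 0.05 * rng.standard_normal(len(mp.values))
                        * (mp.values > 1e-3), 0, None)
        f0 = fit_two_gaussians(MetaProfile(mp.axis, noisy, 100))
        f5 = fit_two_gaussians(MetaProfile(mp.axis, 5 * noisy, 100))
        assert abs(f5.mu1 - f0.mu1) < 1e-6
        assert abs(f5.mu2 - f0.mu2) < 1e-6
        assert abs(f5.sigma1 - f0.sigma1) < 1e-6 * max(1, f0.sigma1)
        assert abs(f5.w - f0.w) < 1e-6
        assert f5.amplitude == pytest.approx(5 * f0.amplitude, rel=1e-6)

    def test_axis_shift_shifts_means(self):
        rng = np.random.default_rng(11)
        mp, _ = truth_profile()
        noisy = np.clip(mp.values + 0.05 * rng.standard_normal(len(mp.values))
                        * (mp.values > 1e-3), 0, None)
        f0 = fit_two_gaussians(MetaProfile(mp.axis, noisy, 100))
        for c in (250.0, -1300.0):
            fc = fit_two_gaussians(MetaProfile(mp.axis + c, noisy, 100))
            assert abs(fc.mu1 - f0.mu1 - c) < 1e-6
            assert abs(fc.mu2 - f0.mu2 - c) < 1e-6

    def test_rss_not_worse_than_any_initialization(self):
        mp, _ = truth_profile(w=0.7)
        fit = fit_two_gaussians(mp)
        # the true parameters give RSS 0; the fit must reach (near) that
        assert fit.rss <= 1e-10


class TestEvaluateBimodal:
    def fit(self, **kw):
        params = dict(mu1=-39.0, sigma1=80.0, mu2=455.0, sigma2=400.0, w=0.4,
                      amplitude=2.0, rss=0.0, converged=True)
        params.update(kw)
        return BimodalFit(**params)

    def test_peak_value_with_degenerate_weight(self):
        f = self.fit(w=1 - 1e-12)
        assert evaluate_bimodal(f, -39.0) == pytest.approx(2.0, abs=1e-9)

    def test_tails_vanish(self):
        f = self.fit()
        assert evaluate_bimodal(f, 1e7) == pytest.approx(0.0, abs=1e-300)
        assert evaluate_bimodal(f, -1e7) == pytest.approx(0.0, abs=1e-300)

    def test_hand_arithmetic(self):
        f = self.fit(mu1=0.0, sigma1=100.0, mu2=400.0, sigma2=200.0, w=0.25,
                     amplitude=3.0)
        x = 100.0
        expected = 3.0 * (
            0.25 * np.exp(-(100.0**2) / (2 * 100.0**2))
            + 0.75 * np.exp(-((100.0 - 400.0) ** 2) / (2 * 200.0**2))
        )
        assert evaluate_bimodal(f, x) == pytest.approx(expected, abs=1e-12)

    def test_weight_bounds_enforced(self):
        with pytest.raises(ValueError):
            self.fit(w=0.0)
        with pytest.raises(ValueError):
            self.fit(sigma1=-1.0)
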