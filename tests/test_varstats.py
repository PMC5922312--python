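"""Variability statistics: density maps, generalized variance, tests."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from welltrack import varstats as vs


class TestDensityMap:
    def test_integral_is_one_for_uniform_cloud(self):
        rng = np.random.default_rng(0)
        pts = rng.uniform(0.1, 0.9, (48, 2))
        assert vs.kernel_density_map(pts).integral() == pytest.approx(
            1.0, abs=0.01)

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=25, deadline=None)
    def test_integral_is_one_for_random_samples(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 200))
        pts = rng.normal(rng.uniform(-3, 3, 2),
                         rng.uniform(0.05, 2.0, 2), (n, 2))
        assert vs.kernel_density_map(pts).integral() == pytest.approx(
            1.0, abs=0.01)

    def test_bandwidth_follows_sixth_root_rule(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(0, 1, (100, 2))
        sx, sy = vs.kde_bandwidths(pts)
        alpha = pts.std(axis=0, ddof=1)
        assert sx == pytest.approx(100 ** (-1 / 6) * alpha[0])
        assert sy == pytest.approx(100 ** (-1 / 6) * alpha[1])

    def test_peak_close_to_product_normal_reference(self):
        # standard-normal sample: the kernel-smoothed peak approaches the
        # product-normal peak with variance inflated by the bandwidth
        rng = np.random.default_rng(2)
        pts = rng.normal(0, 1, (100, 2))
        dmap = vs.kernel_density_map(pts)
        sx, sy = dmap.bandwidths
        ax, ay = pts.std(axis=0, ddof=1)
        ref = 1.0 / (2 * np.pi * np.sqrt((ax ** 2 + sx ** 2)
                                         * (ay ** 2 + sy ** 2)))
        assert dmap.values.max() == pytest.approx(ref, rel=0.2)

    def test_mirror_symmetric_points_give_symmetric_density(self):
        pts = np.array([[0.3, 0.5], [0.7, 0.5], [0.3, 0.5], [0.7, 0.5],
                        [0.5, 0.4], [0.5, 0.6]])
        dmap = vs.kernel_density_map(pts, grid_size=101)
        assert np.abs(dmap.values - dmap.values[:, ::-1]).max() < 1e-9

    def test_degenerate_axis_rejected(self):
        pts = np.column_stack([np.full(10, 0.5),
                               np.linspace(0, 1, 10)])
        with pytest.raises(ValueError, match="degenerate"):
            vs.kernel_density_map(pts)


class TestGeneralizedVariance:
    def test_matches_closed_form_identity(self):
        # |Sigma| must equal sx^2 sy^2 (1 - rho^2) to near machine precision
        rng = np.random.default_rng(3)
        for _ in range(1000):
            n = int(rng.integers(3, 60))
            pts = rng.normal(rng.uniform(-2, 2, 2),
                             rng.uniform(0.1, 3.0, 2), (n, 2))
            pts[:, 1] += rng.uniform(-1, 1) * pts[:, 0]
            gv = vs.generalized_variance(pts)
            vx, vy = pts.var(axis=0, ddof=1)
            rho = np.corrcoef(pts.T)[0, 1]
            ref = vx * vy * (1 - rho ** 2)
            assert abs(gv - ref) <= 1e-10 * max(ref, 1e-300) + 1e-15

    def test_collinear_points_give_zero(self):
        x = np.linspace(0, 1, 10)
        assert vs.generalized_variance(
            np.column_stack([x, 2 * x + 1])) == pytest.approx(0.0, abs=1e-15)

    def test_maximal_at_zero_correlation(self):
        # fixed marginal variances, swept correlation: GV peaks at rho = 0
        rng = np.random.default_rng(4)
        x = rng.normal(size=200)
        z = rng.normal(size=200)
        x = (x - x.mean()) / x.std(ddof=1)
        z -= x * (z @ x) / (x @ x)          # exactly orthogonal
        z = (z - z.mean()) / z.std(ddof=1)
        gvs = []
        for rho in np.linspace(-0.9, 0.9, 13):
            y = rho * x + np.sqrt(1 - rho ** 2) * z
            gvs.append(vs.generalized_variance(np.column_stack([x, y])))
        assert np.argmax(gvs) == 6   # the rho = 0 slot

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            vs.generalized_variance(np.zeros((2, 2)))


class TestEllipse:
    def test_semiaxes_reduce_to_sds_for_diagonal_covariance(self):
        rng = np.random.default_rng(5)
        pts = np.column_stack([rng.normal(0, 2.0, 500),
                               rng.normal(0, 0.5, 500)])
        pts -= pts.mean(axis=0)
        # exact decorrelation so the covariance is diagonal
        pts[:, 1] -= pts[:, 0] * (pts[:, 1] @ pts[:, 0]) / (
            pts[:, 0] @ pts[:, 0])
        ell = vs.individual_ellipse(pts)
        sds = np.sort(pts.std(axis=0, ddof=1))[::-1]
        assert np.allclose(ell.semiaxes, sds, rtol=1e-10)

    def test_isotropic_cloud_nearly_circular(self):
        rng = np.random.default_rng(6)
        ell = vs.individual_ellipse(rng.normal(0, 1, (4000, 2)))
        assert ell.semiaxes[0] / ell.semiaxes[1] < 1.1

    def test_collinear_fragments_collapse_one_axis(self):
        x = np.linspace(0, 1, 8)
        ell = vs.individual_ellipse(np.column_stack([x, -3 * x]))
        assert ell.semiaxes[1] == pytest.approx(0.0, abs=1e-8)

    def test_center_is_fragment_mean(self):
        pts = np.array([[0.0, 0], [1, 1], [2, 0], [1, -1.0]])
        assert vs.individual_ellipse(pts).center == pytest.approx((1.0, 0.0))


class TestVariabilityDistributions:
    def test_identical_constant_individuals_give_zeros(self):
        mat = [np.full(6, 0.4) for _ in range(5)]
        d = vs.variability_distributions(mat, "activity")
        assert np.allclose(d.intra, 0) and np.allclose(d.inter, 0)

    def test_constant_but_distinct_individuals(self):
        mat = [np.full(6, v) for v in (0.2, 0.4, 0.6, 0.8)]
        d = vs.variability_distributions(mat, "activity")
        assert np.allclose(d.intra, 0)
        assert (d.inter > 0).all()

    def test_shuffling_equalizes_intra_and_inter(self):
        rng = np.random.default_rng(7)
        base = rng.uniform(0.2, 0.8, 12)[:, None] + rng.normal(
            0, 0.02, (12, 20))
        flat = rng.permutation(base.ravel()).reshape(base.shape)
        d = vs.variability_distributions(list(flat), "activity")
        assert np.median(d.inter) == pytest.approx(np.median(d.intra),
                                                   rel=0.25)

    def test_signed_parameter_uses_sd(self):
        mat = [np.array([-0.5, 0.5, -0.5, 0.5]) for _ in range(3)]
        d = vs.variability_distributions(mat, "tortuosity")
        assert d.measure == "sd"
        assert np.allclose(d.intra, np.std([-0.5, 0.5, -0.5, 0.5], ddof=1))

    def test_misaligned_fragment_counts_rejected(self):
        with pytest.raises(ValueError, match="counts"):
            vs.variability_distributions(
                [np.zeros(4), np.zeros(5)], "activity")


class TestIntraInterPermutation:
    def _individual_matrix(self, rng, n_ind=12, n_frag=10, spread=0.0):
        centers = 0.5 + spread * rng.standard_normal(n_ind)
        return list(centers[:, None] + rng.normal(0, 0.05, (n_ind, n_frag)))

    def test_null_calibration(self):
        # individuals drawn from one fragment distribution: the test must
        # reject at about its nominal level
        rej = 0
        n_rep = 200
        for seed in range(n_rep):
            rng = np.random.default_rng(1000 + seed)
            frags = self._individual_matrix(rng, spread=0.0)
            res = vs.permutation_test_intra_inter(
                frags, "activity", n_perm=200, seed=seed)
            rej += res.p_value < 0.05
        band = 1.96 * np.sqrt(0.05 * 0.95 / n_rep)
        assert abs(rej / n_rep - 0.05) <= band + 0.01

    def test_strong_individuality_detected(self):
        rng = np.random.default_rng(8)
        frags = self._individual_matrix(rng, spread=0.15)
        res = vs.permutation_test_intra_inter(frags, "activity",
                                              n_perm=1000, seed=0)
        assert res.p_value < 0.01

    def test_seeded_determinism_and_bookkeeping(self):
        rng = np.random.default_rng(9)
        frags = self._individual_matrix(rng, spread=0.05)
        r1 = vs.permutation_test_intra_inter(frags, "activity",
                                             n_perm=1000, seed=42)
        r2 = vs.permutation_test_intra_inter(frags, "activity",
                                             n_perm=1000, seed=42)
        assert r1.p_value == r2.p_value
        assert r1.n_perm == 1000 and len(r1.permuted) == 1000


class TestGroupPermutation:
    def test_identical_groups_give_p_one(self):
        pts = np.random.default_rng(10).uniform(0, 1, (8, 2))
        res = vs.permutation_test_groups(pts, pts.copy(), n_perm=200, seed=0)
        assert res.observed == 0.0
        assert res.p_value == 1.0

    def test_mean_shift_detected_by_mean_statistic(self):
        rng = np.random.default_rng(11)
        a = rng.normal(0.4, 0.05, (24, 2))
        b = rng.normal(0.6, 0.05, (24, 2))
        res = vs.permutation_test_groups(a, b, statistic="mean_diff",
                                         n_perm=500, seed=1)
        assert res.p_value < 0.01

    def test_variance_difference_detected_by_gv_statistic(self):
        rng = np.random.default_rng(12)
        a = rng.normal(0.5, 0.15, (24, 2))
        b = rng.normal(0.5, 0.03, (24, 2))
        res = vs.permutation_test_groups(a, b, n_perm=500, seed=2)
        assert res.p_value < 0.01

    def test_small_groups_rejected(self):
        pts = np.zeros((2, 2))
        with pytest.raises(ValueError):
            vs.permutation_test_groups(pts, pts, n_perm=10)


class TestPolar:
    def test_point_at_population_mean_has_zero_radius(self):
        pts = np.array([[0.5, 0.5], [0.3, 0.5], [0.7, 0.5],
                        [0.5, 0.3], [0.5, 0.7]])
        r, theta = vs.polar_coordinates(pts)
        assert r[0] == pytest.approx(0.0)

    def test_pure_activity_displacement_has_zero_angle(self):
        pts = np.array([[0.8, 0.5], [0.2, 0.5]])
        r, theta = vs.polar_coordinates(pts)
        assert theta[0] == pytest.approx(0.0)
        assert theta[1] == pytest.approx(np.pi)

    def test_pool_values_are_member_means(self):
        rng = np.random.default_rng(13)
        pts = rng.uniform(0, 1, (15, 2))
        pool = [2, 5, 7, 11, 14]
        r_all, t_all = vs.polar_coordinates(pts)
        r_pool, t_pool = vs.polar_coordinates(pts, pools=[pool])
        assert r_pool[0] == pytest.approx(r_all[pool].mean())
        assert t_pool[0] == pytest.approx(t_all[pool].mean())

    def test_empty_pool_rejected(self):
        pts = np.random.default_rng(14).uniform(0, 1, (5, 2))
        with pytest.raises(ValueError, match="empty"):
            vs.polar_coordinates(pts, pools=[[]])


class TestCorrelationTest:
    def test_perfect_linear_relation(self):
        x = np.arange(10.0)
        r, p = vs.correlation_r_test(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        assert p == pytest.approx(0.0, abs=1e-50)

    def test_matches_direct_formula_and_scipy(self):
        x = np.array([1.0, 2.0, 4.0, 4.5, 7.0])
        y = np.array([0.3, 1.1, 0.9, 2.0, 2.2])
        r, p = vs.correlation_r_test(x, y)
        r_ref = np.corrcoef(x, y)[0, 1]
        t_ref = r_ref * np.sqrt(3 / (1 - r_ref ** 2))
        p_ref = 2 * stats.t.sf(abs(t_ref), 3)
        assert abs(r - r_ref) < 1e-12 and abs(p - p_ref) < 1e-12
        r_sp, p_sp = stats.pearsonr(x, y)
        assert abs(r - r_sp) < 1e-12 and abs(p - p_sp) < 1e-9

    def test_null_p_values_are_uniform(self):
        rng = np.random.default_rng(15)
        pvals = []
        for _ in range(500):
            x = rng.normal(size=50)
            y = rng.normal(size=50)
            pvals.append(vs.correlation_r_test(x, y)[1])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            vs.correlation_r_test(np.ones(5), np.arange(5.0))
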