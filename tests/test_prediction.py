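"""GP conditioning at the grid and original-scale predictive draws."""

import numpy as np
import pytest

from roadmoss import (
    conditional_spatial_draws,
    pointwise_map_summaries,
    predictive_concentration_draws,
)
from roadmoss.inference import PosteriorDrawSet
from roadmoss.prediction import ConditionalFieldDraws, PredictiveDrawSet, \
    kriging_conditional_moments
from roadmoss.synthetic import GridPoint


def _fixed_drawset(n_draws, eta_sites, sigma2_sq=0.5, theta=2000.0,
                   beta=(0.0, 0.0, 0.0, 0.0), sigma1_sq=0.1, seed=0):
    """A draw set with constant parameters across draws (and optional
    per-draw eta noise disabled), standing in for a fitted posterior."""
    eta = np.tile(np.asarray(eta_sites, float), (n_draws, 1))
    return PosteriorDrawSet(
        beta=np.tile(np.asarray(beta, float), (n_draws, 1)),
        sigma0_sq=np.full(n_draws, 0.05),
        sigma1_sq=np.full(n_draws, sigma1_sq),
        sigma2_sq=np.full(n_draws, sigma2_sq),
        theta=np.full(n_draws, theta),
        chain=np.zeros(n_draws, dtype=int),
        alpha=np.zeros_like(eta), eta=eta,
        site_ids=[f"S{i}" for i in range(eta.shape[1])])


def _sites_at(coords):
    from roadmoss.core import SiteRecord
    return [SiteRecord(f"S{i}", float(x), float(y), max(abs(y), 1.0),
                       "north" if y >= 0 else "south")
            for i, (x, y) in enumerate(coords)]


def _grid_at(coords, distance=1000.0, side="north", stratum=2):
    return [GridPoint(f"G{i}", float(x), float(y), distance, side, stratum)
            for i, (x, y) in enumerate(coords)]


SITE_XY = [(0, 200), (800, -300), (1500, 600), (2500, -100), (4000, 400)]
GRID_XY = [(400, 100), (1800, 300), (3200, -200)]


class TestKrigingMoments:
    def test_matches_brute_force_partitioned_conditioning(self):
        """Conditional mean/covariance at 3 grid points given 5 sites equals
        brute-force joint-Gaussian conditioning to 1e-8."""
        rng = np.random.default_rng(12)
        eta = rng.normal(0, 0.7, 5)
        s2, theta = 0.8, 1500.0
        mean, cov = kriging_conditional_moments(
            np.array(SITE_XY, float), np.array(GRID_XY, float), eta, s2, theta)

        # oracle: build the full joint covariance and partition it
        allxy = np.array(SITE_XY + GRID_XY, float)
        d = np.sqrt(((allxy[:, None] - allxy[None]) ** 2).sum(-1))
        C = s2 * np.exp(-d / theta)
        C[:5, :5] += 1e-8 * s2 * np.eye(5)
        Css, Csg = C[:5, :5], C[:5, 5:]
        Cgg = C[5:, 5:]
        mean_o = Csg.T @ np.linalg.solve(Css, eta)
        cov_o = Cgg - Csg.T @ np.linalg.solve(Css, Csg)
        np.testing.assert_allclose(mean, mean_o, atol=1e-8)
        np.testing.assert_allclose(cov, cov_o, atol=1e-8)


class TestConditionalDraws:
    def test_coincident_grid_point_reproduces_site_field(self):
        """A grid point on top of a site gets that site's field value
        (conditional variance is zero up to jitter)."""
        eta = np.array([0.9, -0.4, 0.2, 0.5, -0.8])
        ds = _fixed_drawset(50, eta)
        grid = _grid_at([SITE_XY[2]])
        out = conditional_spatial_draws(ds, _sites_at(SITE_XY), grid, K=50, seed=1)
        np.testing.assert_allclose(out.values[:, 0], eta[2], atol=1e-2)

    def test_far_point_reverts_to_marginal(self):
        """Far from every site the conditional reverts to N(0, sigma2_sq)."""
        eta = np.array([0.9, -0.4, 0.2, 0.5, -0.8])
        s2 = 0.5
        K = 4000
        ds = _fixed_drawset(K, eta, sigma2_sq=s2, theta=500.0)
        grid = _grid_at([(100000.0, 50000.0)], distance=40000.0, side="south",
                        stratum=5)
        out = conditional_spatial_draws(ds, _sites_at(SITE_XY), grid, K=K, seed=2)
        v = out.values[:, 0]
        se_mean = np.sqrt(s2 / K)
        assert abs(v.mean()) < 3 * se_mean
        se_var = s2 * np.sqrt(2 / K)
        assert abs(v.var() - s2) < 3 * se_var

    def test_block_partition_does_not_change_draws(self):
        """Blocked factorization is algebraically one joint factorization:
        different block sizes give identical draws to 1e-8."""
        rng = np.random.default_rng(3)
        eta = rng.normal(0, 0.5, 5)
        ds = _fixed_drawset(20, eta)
        grid = _grid_at([(200.0 * i, 50.0 * ((-1) ** i)) for i in range(23)])
        sites = _sites_at(SITE_XY)
        a = conditional_spatial_draws(ds, sites, grid, K=20, seed=4, block_size=5)
        b = conditional_spatial_draws(ds, sites, grid, K=20, seed=4, block_size=1000)
        np.testing.assert_allclose(a.values, b.values, atol=1e-8)

    def test_draws_match_conditional_moments(self):
        """Empirical mean/covariance of many draws agree with the exact
        conditional moments (Monte-Carlo tolerance)."""
        rng = np.random.default_rng(5)
        eta = rng.normal(0, 0.7, 5)
        K = 6000
        ds = _fixed_drawset(K, eta, sigma2_sq=0.8, theta=1500.0)
        sites = _sites_at(SITE_XY)
        grid = _grid_at(GRID_XY)
        out = conditional_spatial_draws(ds, sites, grid, K=K, seed=6)
        mean, cov = kriging_conditional_moments(
            np.array(SITE_XY, float), np.array(GRID_XY, float), eta, 0.8, 1500.0)
        se = np.sqrt(np.diag(cov) / K)
        np.testing.assert_array_less(np.abs(out.values.mean(0) - mean), 4 * se + 1e-9)
        np.testing.assert_allclose(np.cov(out.values.T), cov, atol=0.05)

    def test_marginal_variance_never_exceeds_sill(self):
        """Conditioning only removes variance: diag of the conditional
        covariance is bounded by sigma2_sq (+ jitter)."""
        rng = np.random.default_rng(7)
        for _ in range(10):
            site_xy = rng.uniform(0, 5000, (6, 2))
            grid_xy = rng.uniform(0, 5000, (4, 2))
            s2 = float(rng.uniform(0.1, 2.0))
            _, cov = kriging_conditional_moments(
                site_xy, grid_xy, rng.normal(size=6), s2,
                float(rng.uniform(200, 5000)))
            assert np.all(np.diag(cov) <= s2 * (1 + 1e-6))

    def test_k_exceeding_retained_draws_rejected(self):
        ds = _fixed_drawset(10, np.zeros(5))
        with pytest.raises(ValueError):
            conditional_spatial_draws(ds, _sites_at(SITE_XY), _grid_at(GRID_XY),
                                      K=11)

    def test_empty_grid_rejected(self):
        ds = _fixed_drawset(10, np.zeros(5))
        with pytest.raises(ValueError):
            conditional_spatial_draws(ds, _sites_at(SITE_XY), [], K=5)


class TestPredictiveDraws:
    def test_all_zero_gives_unit_concentration(self):
        ds = _fixed_drawset(5, np.zeros(5))
        grid = _grid_at(GRID_XY)
        eta_star = ConditionalFieldDraws(np.zeros((5, 3)), np.arange(5))
        out = predictive_concentration_draws(ds, grid, eta_star,
                                             include_new_site_effect=False)
        np.testing.assert_array_equal(out.values, 1.0)

    def test_single_draw_scalar_example(self):
        beta = (9.165, -0.535, -0.766, 0.059)
        ds = _fixed_drawset(1, np.zeros(5), beta=beta)
        grid = [GridPoint("G0", 0.0, 1000.0, 1000.0, "north", 2)]
        eta_star = ConditionalFieldDraws(np.zeros((1, 1)), np.array([0]))
        out = predictive_concentration_draws(ds, grid, eta_star,
                                             include_new_site_effect=False)
        expected = np.exp(9.165 - 0.535 * np.log(1000.0))
        assert out.values[0, 0] == pytest.approx(expected, rel=1e-12)

    def test_monotone_decreasing_along_one_side(self):
        ds = _fixed_drawset(1, np.zeros(5), beta=(9.0, -0.5, -0.7, 0.0))
        distances = [150.0, 400.0, 1000.0, 1900.0]
        grid = [GridPoint(f"G{i}", 0.0, d, d, "north", 2)
                for i, d in enumerate(distances)]
        eta_star = ConditionalFieldDraws(np.zeros((1, 4)), np.array([0]))
        v = predictive_concentration_draws(ds, grid, eta_star,
                                           include_new_site_effect=False).values[0]
        assert np.all(np.diff(v) < 0)

    def test_exp_transform_preserves_draw_ranking(self):
        """Ranking of concentration draws at a point equals the ranking of
        the log-scale values (monotone transform invariance)."""
        rng = np.random.default_rng(8)
        K = 40
        ds = _fixed_drawset(K, np.zeros(5), beta=(5.0, -0.5, 0.0, 0.0))
        grid = _grid_at(GRID_XY)
        eta_star = ConditionalFieldDraws(rng.normal(0, 1, (K, 3)), np.arange(K))
        out = predictive_concentration_draws(ds, grid, eta_star,
                                             include_new_site_effect=False)
        for j in range(3):
            log_scale = eta_star.values[:, j]
            assert np.array_equal(np.argsort(out.values[:, j]),
                                  np.argsort(log_scale))

    def test_sill_to_zero_collapses_to_regression_surface(self):
        """With the new-site effect off and a vanishing sill, draws equal
        exp(x'beta) draw-wise."""
        rng = np.random.default_rng(9)
        K = 30
        beta_draws = rng.normal(0, 0.2, (K, 4)) + np.array([8.0, -0.5, -0.6, 0.05])
        ds = PosteriorDrawSet(
            beta=beta_draws, sigma0_sq=np.full(K, 0.05),
            sigma1_sq=np.full(K, 0.1), sigma2_sq=np.full(K, 1e-12),
            theta=np.full(K, 2000.0), chain=np.zeros(K, int),
            alpha=np.zeros((K, 5)), eta=np.zeros((K, 5)),
            site_ids=[f"S{i}" for i in range(5)])
        sites = _sites_at(SITE_XY)
        grid = _grid_at(GRID_XY, distance=700.0)
        eta_star = conditional_spatial_draws(ds, sites, grid, K=K, seed=10)
        out = predictive_concentration_draws(ds, grid, eta_star,
                                             include_new_site_effect=False)
        x = np.array([1.0, np.log(700.0), 0.0, 0.0])
        expected = np.exp(beta_draws @ x)
        for j in range(3):
            np.testing.assert_allclose(out.values[:, j], expected, rtol=1e-4)

    def test_misaligned_parent_indices_rejected(self):
        ds = _fixed_drawset(5, np.zeros(5))
        eta_star = ConditionalFieldDraws(np.zeros((5, 3)), np.array([0, 1, 2, 3, 9]))
        with pytest.raises(ValueError):
            predictive_concentration_draws(ds, _grid_at(GRID_XY), eta_star)


def _order_statistic_quantile(x, p):
    """Type-7 quantile by explicit order statistics (test-side oracle)."""
    s = np.sort(np.asarray(x, float))
    h = (len(s) - 1) * p
    lo = int(np.floor(h))
    hi = min(lo + 1, len(s) - 1)
    return s[lo] + (h - lo) * (s[hi] - s[lo])


class TestMapSummaries:
    def _pds(self, values):
        values = np.asarray(values, float)
        return PredictiveDrawSet(values=values,
                                 parent_indices=np.arange(values.shape[0]),
                                 grid_ids=[f"G{j}" for j in range(values.shape[1])])

    def test_constant_draws(self):
        out = pointwise_map_summaries(self._pds(np.full((10, 2), 3.5)))
        assert (out["mean"] == 3.5).all()
        assert (out["q2.5"] == 3.5).all() and (out["q97.5"] == 3.5).all()

    def test_quantiles_match_order_statistics_oracle(self):
        x = np.arange(1.0, 101.0)
        out = pointwise_map_summaries(self._pds(x[:, None]))
        assert out.loc[0, "q2.5"] == pytest.approx(_order_statistic_quantile(x, 0.025))
        assert out.loc[0, "q97.5"] == pytest.approx(_order_statistic_quantile(x, 0.975))
        rng = np.random.default_rng(11)
        y = rng.lognormal(1.0, 0.8, size=77)
        out = pointwise_map_summaries(self._pds(y[:, None]))
        assert out.loc[0, "q2.5"] == pytest.approx(_order_statistic_quantile(y, 0.025))
        assert out.loc[0, "q97.5"] == pytest.approx(_order_statistic_quantile(y, 0.975))

    def test_mean_example(self):
        out = pointwise_map_summaries(self._pds(np.array([[10.0], [20.0], [30.0]])))
        assert out.loc[0, "mean"] == 20.0

    def test_lower_never_exceeds_upper(self):
        rng = np.random.default_rng(12)
        out = pointwise_map_summaries(self._pds(rng.lognormal(0, 1, (50, 8))))
        assert (out["q2.5"] <= out["q97.5"]).all()

    def test_single_draw_rejected(self):
        with pytest.raises(ValueError):
            pointwise_map_summaries(self._pds(np.ones((1, 2))))
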