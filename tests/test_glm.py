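"""GLM posterior adjustment: retention, fit, densities, marginal density."""

import math

import numpy as np
import pytest

from abckit import (EstimationError, GLMFit, LinearGaussianModel,
                    ObservedStats, PosteriorDensity, PriorSpec, RetainedSet,
                    SimulationTable, bayes_factor, estimate, fit_glm,
                    glm_posterior, log_marginal_density, marginal_density,
                    model_check_pvalue, rejection_sample, retain,
                    to_estimation_scale)


def _table(params, stats):
    params, stats = np.atleast_2d(params), np.atleast_2d(stats)
    pn = [f"p{i}" for i in range(params.shape[1])]
    sn = [f"s{i}" for i in range(stats.shape[1])]
    return SimulationTable(column_names=pn + sn,
                           values=np.column_stack([params, stats]),
                           param_names=pn, stat_names=sn)


def _retained(params, stats, weights=None):
    params, stats = np.atleast_2d(params), np.atleast_2d(stats)
    n = params.shape[0]
    w = np.full(n, 1.0 / n) if weights is None else np.asarray(weights) / np.sum(weights)
    return RetainedSet(param_names=[f"p{i}" for i in range(params.shape[1])],
                       stat_names=[f"s{i}" for i in range(stats.shape[1])],
                       params=params, stats=stats,
                       distances=np.zeros(n), weights=w)


class TestRetain:
    def test_whole_table_retained_when_j_equals_rows(self, rng):
        table = _table(rng.normal(size=(10, 1)), rng.normal(size=(10, 1)))
        obs = ObservedStats(names=["s0"], values=[0.0])
        kept = retain(table, obs, count=10)
        assert kept.J == 10

    def test_matches_exhaustive_sort(self, rng):
        stats = rng.normal(size=(10, 2))
        table = _table(rng.normal(size=(10, 1)), stats)
        obs = ObservedStats(names=["s0", "s1"], values=[0.3, -0.2])
        kept = retain(table, obs, count=6)
        sds = stats.std(axis=0, ddof=1)
        d = np.sqrt((((stats - obs.values) / sds) ** 2).sum(axis=1))
        expected = np.sort(d)[:6]
        assert np.allclose(kept.distances, expected)
        assert np.all(np.diff(kept.distances) >= 0)

    def test_j_zero_is_error(self, rng):
        table = _table(rng.normal(size=(10, 1)), rng.normal(size=(10, 1)))
        obs = ObservedStats(names=["s0"], values=[0.0])
        with pytest.raises(EstimationError, match="at least"):
            retain(table, obs, count=0)

    def test_ties_broken_by_row_order(self):
        stats = np.array([[1.0], [1.0], [-1.0], [-1.0], [2.0], [0.5]])
        table = _table(np.arange(6.0)[:, None], stats)
        obs = ObservedStats(names=["s0"], values=[0.0])
        kept = retain(table, obs, count=4)
        # |d| ties at rows 0,1,2,3; row 5 closest
        assert list(kept.params[:, 0]) == [5.0, 0.0, 1.0, 2.0]

    def test_count_wins_over_fraction(self, rng):
        table = _table(rng.normal(size=(20, 1)), rng.normal(size=(20, 1)))
        obs = ObservedStats(names=["s0"], values=[0.0])
        kept = retain(table, obs, count=5, fraction=0.9)
        assert kept.J == 5


class TestFitGLM:
    def test_noise_free_linear_data_recovered_exactly(self, rng):
        theta = rng.normal(size=(50, 1))
        stats = 1.0 + 2.0 * theta
        fit = fit_glm(_retained(theta, stats))
        assert fit.c0[0] == pytest.approx(1.0, abs=1e-10)
        assert fit.coef[0, 0] == pytest.approx(2.0, abs=1e-10)
        assert fit.sigma_s[0, 0] > 0  # regularized floor keeps it invertible
        assert fit.sigma_s[0, 0] < 1e-6

    def test_constant_parameter_is_rank_deficiency_error(self, rng):
        theta = np.full((30, 1), 2.0)
        stats = rng.normal(size=(30, 1))
        with pytest.raises(EstimationError, match="collinear.*p0"):
            fit_glm(_retained(theta, stats))

    def test_matches_normal_equations_oracle(self, rng):
        theta = rng.normal(size=(200, 2))
        coef = rng.normal(size=(3, 2))
        stats = 0.5 + theta @ coef.T + 0.2 * rng.normal(size=(200, 3))
        fit = fit_glm(_retained(theta, stats))
        x = np.column_stack([np.ones(200), theta])
        beta = np.linalg.solve(x.T @ x, x.T @ stats)
        assert np.allclose(fit.c0, beta[0], rtol=1e-8)
        assert np.allclose(fit.coef, beta[1:].T, rtol=1e-8)
        resid = stats - x @ beta
        assert np.allclose(fit.sigma_s, resid.T @ resid / (200 - 3), rtol=1e-8)

    def test_too_few_rows_rejected(self, rng):
        with pytest.raises(EstimationError, match="minimum"):
            fit_glm(_retained(rng.normal(size=(3, 1)), rng.normal(size=(3, 1))))


class TestGLMPosterior:
    def test_uninformative_statistics_give_smoothed_parameter_cloud(self, rng):
        # C = 0 forces the posterior to the kernel density of retained thetas
        theta = rng.normal(size=(200, 1))
        retained = _retained(theta, rng.normal(size=(200, 1)))
        fit = GLMFit(c0=np.zeros(1), coef=np.zeros((1, 1)), sigma_s=np.eye(1),
                     param_names=["p0"], stat_names=["s0"])
        bw = np.array([0.3])
        (density,) = glm_posterior(fit, retained, [], np.zeros(1), bandwidth=bw)
        kde = np.mean(
            np.exp(-0.5 * ((density.grid[:, None] - theta.ravel()) / 0.3) ** 2),
            axis=1) / (0.3 * math.sqrt(2 * math.pi))
        kde /= np.trapezoid(kde, density.grid)
        assert np.allclose(density.densities, kde, rtol=1e-8, atol=1e-12)

    def test_density_integrates_to_one(self, rng):
        theta = rng.normal(size=(100, 1))
        stats = 1.0 + 2.0 * theta + 0.5 * rng.normal(size=(100, 1))
        fit = fit_glm(_retained(theta, stats))
        (density,) = glm_posterior(fit, _retained(theta, stats), [], np.array([1.5]))
        assert density.integral() == pytest.approx(1.0, abs=1e-6)

    def test_conjugate_oracle_small(self, rng, linear_gaussian_1d):
        # s = 0.5 + 2 theta + eps, sd 2; flat prior; posterior N((s-0.5)/2, 1)
        specs = [PriorSpec("theta", "uniform", (-10, 10))]
        table = rejection_sample(20_000, specs, linear_gaussian_1d, rng)
        obs = ObservedStats(names=linear_gaussian_1d.stat_names, values=[4.5])
        result = estimate(table, obs, specs, count=2_000)
        density = result.posteriors["theta"]
        assert density.mean() == pytest.approx(2.0, abs=0.1)
        assert density.sd() == pytest.approx(1.0, abs=0.12)

    def test_posterior_invariant_to_row_order(self, rng):
        theta = rng.normal(size=(60, 1))
        stats = theta + 0.3 * rng.normal(size=(60, 1))
        retained = _retained(theta, stats)
        perm = rng.permutation(60)
        shuffled = _retained(theta[perm], stats[perm])
        fit = fit_glm(retained)
        bw = np.array([0.2])
        (a,) = glm_posterior(fit, retained, [], np.array([0.1]), bandwidth=bw)
        (b,) = glm_posterior(fit_glm(shuffled), shuffled, [], np.array([0.1]),
                             bandwidth=bw)
        assert np.allclose(a.grid, b.grid) and np.allclose(a.densities, b.densities)

    def test_log_scale_parameter_estimated_on_log10_scale(self, rng):
        specs = [PriorSpec("rate", "log10uniform", (-1, 1))]
        model = LinearGaussianModel([0.0], [[1.0]], [[0.04]])
        # simulate on the natural scale: stat = rate + noise
        table = rejection_sample(5_000, specs, model, rng)
        obs = ObservedStats(names=model.stat_names, values=[1.0])
        result = estimate(table, obs, specs, count=1_000)
        density = result.posteriors["rate"]
        assert density.log10_scale
        assert density.grid[0] >= -1.0 and density.grid[-1] <= 1.0
        # back-transform is monotone: natural mode = 10 ** (log-scale mode)
        assert density.to_natural_scale_value(density.mode()) == \
            pytest.approx(10.0 ** density.mode())

    def test_to_estimation_scale_log_transforms_flagged_columns(self):
        retained = _retained(np.array([[10.0], [100.0]]), np.zeros((2, 1)))
        retained.param_names[0] = "rate"
        spec = PriorSpec("rate", "log10uniform", (0, 3))
        out = to_estimation_scale(retained, [spec])
        assert np.allclose(out.params[:, 0], [1.0, 2.0])


class TestMarginalDensity:
    def test_single_component_uninformative_is_gaussian_at_c0(self):
        retained = _retained(np.zeros((1, 1)), np.zeros((1, 1)))
        fit = GLMFit(c0=np.array([2.0]), coef=np.zeros((1, 1)),
                     sigma_s=np.array([[4.0]]), param_names=["p0"],
                     stat_names=["s0"])
        bw = np.array([1.0])
        value = marginal_density(fit, retained, bw, np.array([2.0]))
        assert value == pytest.approx(1.0 / math.sqrt(2 * math.pi * 4.0), rel=1e-12)

    def test_density_decreases_away_from_component_means(self, rng):
        theta = rng.normal(size=(50, 1))
        stats = theta + 0.1 * rng.normal(size=(50, 1))
        retained = _retained(theta, stats)
        fit = fit_glm(retained)
        bw = np.array([0.2])
        near = marginal_density(fit, retained, bw,
                                fit.c0 + fit.coef @ retained.params[0])
        far = marginal_density(fit, retained, bw, np.array([50.0]))
        assert near > far

    def test_matches_quadrature_oracle(self, rng):
        # 1-D: integrate Normal(s; c0 + C t, sigma) against the mixture prior
        theta = rng.normal(size=(30, 1))
        retained = _retained(theta, theta)
        c0, coef, sig2, bw = 0.3, 1.7, 0.8, 0.25
        fit = GLMFit(c0=np.array([c0]), coef=np.array([[coef]]),
                     sigma_s=np.array([[sig2]]), param_names=["p0"],
                     stat_names=["s0"])
        s = 0.9
        value = marginal_density(fit, retained, np.array([bw]), np.array([s]))
        nodes = np.linspace(theta.min() - 6 * bw, theta.max() + 6 * bw, 10_001)
        prior = np.mean(np.exp(-0.5 * ((nodes[:, None] - theta.ravel()) / bw) ** 2),
                        axis=1) / (bw * math.sqrt(2 * math.pi))
        lik = np.exp(-0.5 * (s - c0 - coef * nodes) ** 2 / sig2) \
            / math.sqrt(2 * math.pi * sig2)
        expected = np.trapezoid(lik * prior, nodes)
        assert value == pytest.approx(expected, rel=1e-3)

    def test_marginal_density_integrates_to_one_in_1d(self, rng):
        theta = rng.normal(size=(20, 1))
        retained = _retained(theta, theta)
        fit = GLMFit(c0=np.zeros(1), coef=np.array([[1.0]]),
                     sigma_s=np.array([[0.5]]), param_names=["p0"],
                     stat_names=["s0"])
        grid = np.linspace(-15, 15, 4_001)
        dens = [marginal_density(fit, retained, np.array([0.3]), np.array([g]))
                for g in grid]
        assert np.trapezoid(dens, grid) == pytest.approx(1.0, abs=1e-6)


class TestBayesFactor:
    def test_identical_models_give_one(self):
        assert bayes_factor(0.37, 0.37) == 1.0

    def test_ratio_arithmetic(self):
        assert bayes_factor(0.4, 0.1) == pytest.approx(4.0)

    def test_zero_denominator_is_error(self):
        with pytest.raises(EstimationError, match="zero marginal"):
            bayes_factor(0.4, 0.0)

    def test_correct_model_usually_wins(self, rng):
        # model A generates the data; model B is shifted far off it
        from abckit import default_bandwidth
        specs = [PriorSpec("theta", "uniform", (-5, 5))]
        model_a = LinearGaussianModel([0.0], [[1.0]], [[1.0]])
        model_b = LinearGaussianModel([15.0], [[1.0]], [[1.0]])
        tables = {m: rejection_sample(2_000, specs, m, rng)
                  for m in (model_a, model_b)}

        def log_marg(table, obs):
            kept = retain(table, obs, count=1_000)
            fit = fit_glm(kept)
            bw = default_bandwidth(kept)
            return log_marginal_density(fit, kept, bw,
                                        obs.values_for(kept.stat_names))

        wins = 0
        for _ in range(100):
            theta = specs[0].sample(rng)
            s_obs = model_a.simulate(np.array([theta]), rng)
            obs = ObservedStats(names=model_a.stat_names, values=s_obs)
            if log_marg(tables[model_a], obs) > log_marg(tables[model_b], obs):
                wins += 1
        assert wins >= 95


class TestModelCheckPValue:
    def _fitted(self, rng, n=100):
        theta = rng.normal(size=(n, 1))
        stats = theta + 0.5 * rng.normal(size=(n, 1))
        retained = _retained(theta, stats)
        return fit_glm(retained), retained

    def test_highest_density_row_gives_p_one(self, rng):
        fit, retained = self._fitted(rng)
        bw = np.array([0.2])
        dens = [log_marginal_density(fit, retained, bw, s) for s in retained.stats]
        best = retained.stats[int(np.argmax(dens))]
        assert model_check_pvalue(fit, retained, bw, best) == pytest.approx(1.0)

    def test_far_outlier_gives_p_zero(self, rng):
        fit, retained = self._fitted(rng)
        bw = np.array([0.2])
        outlier = retained.stats.mean(axis=0) + 10 * retained.stats.std(axis=0)
        assert model_check_pvalue(fit, retained, bw, outlier) == 0.0

    def test_p_is_a_weighted_rank(self, rng):
        fit, retained = self._fitted(rng, n=50)
        bw = np.array([0.2])
        dens = np.array([log_marginal_density(fit, retained, bw, s)
                         for s in retained.stats])
        s_obs = retained.stats[10]
        expected = np.mean(dens <= dens[10])
        assert model_check_pvalue(fit, retained, bw, s_obs) == pytest.approx(expected)


class TestDensitySummaries:
    def _density(self, grid, dens):
        dens = np.asarray(dens, float)
        dens = dens / np.trapezoid(dens, grid)
        return PosteriorDensity("x", np.asarray(grid, float), dens)

    def test_hpdi_five_cell_oracle(self):
        # trapezoid cell masses {0.4, 0.3, 0.15, 0.1, 0.05}: mass 0.5 -> cells 1-2
        density = self._density([0.0, 1.0, 2.0, 3.0, 4.0],
                                [0.8, 0.3, 0.15, 0.1, 0.1])
        intervals = density.hpdi(0.5)
        assert intervals == [(0.0, 1.0)]

    def test_hpdi_symmetric_triangle(self):
        grid = np.linspace(0.0, 1.0, 201)
        density = self._density(grid, 1.0 - np.abs(grid - 0.5))
        ((lo, hi),) = density.hpdi(0.5)
        assert lo + hi == pytest.approx(1.0, abs=0.02)

    def test_hpdi_mass_near_one_covers_grid(self):
        grid = np.linspace(-1.0, 1.0, 101)
        density = self._density(grid, np.exp(-grid ** 2))
        ((lo, hi),) = density.hpdi(0.999)
        assert lo == grid[0] and hi == grid[-1]

    def test_bimodal_density_yields_two_intervals(self):
        grid = np.linspace(-3.0, 3.0, 301)
        dens = np.exp(-0.5 * ((grid + 1.5) / 0.2) ** 2) \
            + np.exp(-0.5 * ((grid - 1.5) / 0.2) ** 2)
        assert len(self._density(grid, dens).hpdi(0.6)) == 2

    def test_mode_ties_break_toward_smaller_value(self, caplog):
        density = self._density([0.0, 1.0, 2.0], [1.0, 1.0, 1.0])
        with caplog.at_level("WARNING"):
            assert density.mode() == 0.0
        assert "tied" in caplog.text

    def test_mode_matches_linear_scan(self, rng):
        grid = np.linspace(0, 1, 50)
        dens = rng.uniform(0.1, 1.0, 50)
        density = self._density(grid, dens)
        assert density.mode() == grid[int(np.argmax(density.densities))]
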