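"""GP surrogate, marginal likelihood, expected improvement, closed loop."""

import numpy as np
import pytest
from scipy.stats import multivariate_normal, norm

from boldopt.bayesopt import (
    GpModel,
    KernelParams,
    expected_improvement,
    gp_predict,
    kernel,
    kernel_matrix,
    log_marginal_likelihood,
    propose_next,
    run_bayesopt,
    tune_hyperparams,
)


@pytest.fixture
def params():
    return KernelParams(signal_sd=1.0, length_scales=(3.0, 3.0), noise_variance=0.01)


class TestKernel:
    def test_zero_distance_gives_signal_variance(self, params):
        assert kernel((3, 4), (3, 4), params) == pytest.approx(1.0)
        p2 = KernelParams(2.5, (3.0, 3.0), 0.0)
        assert kernel((1, 1), (1, 1), p2) == pytest.approx(6.25)

    def test_unit_distance_closed_form(self):
        p = KernelParams(1.0, (1.0, 1.0), 0.0)
        assert kernel((0, 0), (1, 0), p) == pytest.approx(np.exp(-0.5), abs=1e-9)

    def test_symmetry_and_ard(self):
        p = KernelParams(1.0, (2.0, 5.0), 0.0)
        assert kernel((1, 1), (3, 4), p) == pytest.approx(kernel((3, 4), (1, 1), p))
        # distance along the long-length-scale axis decays less
        assert kernel((0, 0), (0, 3), p) > kernel((0, 0), (3, 0), p)

    def test_gram_matrix_positive_semidefinite(self, rng, params):
        X = rng.uniform(1, 19, size=(20, 2))
        K = kernel_matrix(X, X, params)
        assert np.allclose(K, K.T)
        assert np.linalg.eigvalsh(K).min() > -1e-8


class TestGpPredict:
    def test_single_observation_closed_form(self):
        # with one observation the centered target is zero, so the
        # posterior mean equals the observation everywhere it matters
        p = KernelParams(1.0, (3.0, 3.0), 0.5)
        m = GpModel(params=p, X=[[5, 5]], y=[2.0])
        mean, var = gp_predict(m, [[5, 5]])
        assert mean[0] == pytest.approx(2.0)
        assert var[0] == pytest.approx(1.0 - 1.0 / 1.5)

    def test_noiseless_interpolation(self, rng):
        p = KernelParams(1.0, (3.0, 3.0), 0.0)
        X = [[2, 2], [5, 9], [12, 4], [17, 17]]
        y = rng.normal(size=4)
        m = GpModel(params=p, X=X, y=y)
        mean, var = gp_predict(m, X)
        assert np.allclose(mean, y, atol=1e-6)
        assert np.all(var < 1e-6)

    def test_matches_dense_solve_oracle(self, rng):
        for _ in range(15):
            p = KernelParams(
                float(rng.uniform(0.5, 2)),
                (float(rng.uniform(1, 6)), float(rng.uniform(1, 6))),
                float(rng.uniform(0.01, 1)),
            )
            n = int(rng.integers(3, 12))
            X = rng.uniform(1, 19, size=(n, 2))
            y = rng.normal(size=n)
            Xs = rng.uniform(1, 19, size=(7, 2))
            m = GpModel(params=p, X=X, y=y)
            mean, var = gp_predict(m, Xs)
            # textbook posterior via direct dense solve
            K = kernel_matrix(X, X, p) + p.noise_variance * np.eye(n)
            Ks = kernel_matrix(Xs, X, p)
            yc = y - y.mean()
            mean_o = y.mean() + Ks @ np.linalg.solve(K, yc)
            var_o = p.signal_sd**2 - np.einsum(
                "ij,ji->i", Ks, np.linalg.solve(K, Ks.T)
            )
            assert np.allclose(mean, mean_o, atol=1e-6)
            assert np.allclose(var, np.clip(var_o, 0, None), atol=1e-6)

    def test_variance_nonincreasing_with_observations(self, study2, rng):
        p = KernelParams(1.0, (4.0, 4.0), 0.25)
        cand = study2.positions()
        m = GpModel(params=p)
        _, prev = gp_predict(m, cand)
        for k in range(12):
            coord = cand[rng.integers(len(cand))]
            m.add_observation(coord, float(rng.normal()))
            _, var = gp_predict(m, cand)
            assert np.all(var <= prev + 1e-8)
            prev = var


class TestLogMarginalLikelihood:
    def test_matches_gaussian_logpdf_oracle(self, rng, params):
        X = rng.uniform(1, 19, size=(6, 2))
        y = rng.normal(size=6)
        ours = log_marginal_likelihood(X, y, params)
        K = kernel_matrix(X, X, params) + params.noise_variance * np.eye(6)
        oracle = multivariate_normal(mean=np.zeros(6), cov=K).logpdf(y - y.mean())
        assert ours == pytest.approx(oracle, abs=1e-6)

    def test_invariant_to_permutation(self, rng, params):
        X = rng.uniform(1, 19, size=(8, 2))
        y = rng.normal(size=8)
        perm = rng.permutation(8)
        assert log_marginal_likelihood(X, y, params) == pytest.approx(
            log_marginal_likelihood(X[perm], y[perm], params), abs=1e-9
        )

    def test_gross_noise_inflation_lowers_likelihood(self, rng):
        p = KernelParams(1.0, (3.0, 3.0), 1e-4)
        X = np.array([[i, j] for i in range(1, 6) for j in range(1, 6)], dtype=float)
        K = kernel_matrix(X, X, p)
        y = np.linalg.cholesky(K + 1e-10 * np.eye(25)) @ rng.standard_normal(25)
        inflated = KernelParams(1.0, (3.0, 3.0), 1e-4 * 1e6)
        assert log_marginal_likelihood(X, y, p) > log_marginal_likelihood(X, y, inflated)


class TestTuneHyperparams:
    def test_recovers_known_parameters(self, study2):
        # sigma=1, l=(3,3), sigma_noise=0.1: length scales within factor 2
        true = KernelParams(1.0, (3.0, 3.0), 0.01)
        cand = study2.positions().astype(float)
        ok = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            idx = rng.choice(len(cand), 50, replace=False)
            X = cand[idx]
            K = kernel_matrix(X, X, true) + 1e-10 * np.eye(50)
            y = np.linalg.cholesky(K) @ rng.standard_normal(50) + rng.normal(0, 0.1, 50)
            fit = tune_hyperparams(X, y, seed=seed)
            ratios = np.array(fit.length_scales) / 3.0
            if np.all((ratios > 0.5) & (ratios < 2.0)):
                ok += 1
        assert ok >= 8

    def test_beats_random_parameter_draws(self, study2, rng):
        cand = study2.positions().astype(float)
        idx = rng.choice(len(cand), 30, replace=False)
        X = cand[idx]
        y = rng.normal(size=30)
        fit = tune_hyperparams(X, y, seed=1, n_restarts=4)
        best_fit = log_marginal_likelihood(X, y, fit)
        for _ in range(100):
            p = KernelParams(
                float(rng.uniform(0.01, 10)),
                (float(rng.uniform(0.5, 30)), float(rng.uniform(0.5, 30))),
                float(rng.uniform(1e-4, 10)) ** 2,
            )
            assert log_marginal_likelihood(X, y, p) <= best_fit + 1e-6

    def test_deterministic_for_fixed_seed(self, study2, rng):
        cand = study2.positions().astype(float)
        idx = rng.choice(len(cand), 20, replace=False)
        y = rng.normal(size=20)
        a = tune_hyperparams(cand[idx], y, seed=3)
        b = tune_hyperparams(cand[idx], y, seed=3)
        assert a == b


class TestExpectedImprovement:
    def test_at_incumbent_with_unit_sd(self):
        assert expected_improvement(0.0, 1.0, 0.0) == pytest.approx(
            1 / np.sqrt(2 * np.pi), abs=1e-9
        )

    def test_zero_uncertainty_below_incumbent(self):
        assert expected_improvement(0.3, 0.0, 0.5) == 0.0
        assert expected_improvement(0.7, 0.0, 0.5) == pytest.approx(0.2)

    def test_matches_quadrature_oracle(self):
        # E[max(Y - f_max, 0)], Y ~ N(0.3, 0.7^2), f_max = 0.5 by
        # high-resolution deterministic quadrature over 10^6 nodes
        m, s, fmax = 0.3, 0.7, 0.5
        ygrid = np.linspace(m - 10 * s, m + 10 * s, 1_000_001)
        oracle = np.trapezoid(
            np.maximum(ygrid - fmax, 0.0) * norm.pdf(ygrid, m, s), ygrid
        )
        ours = expected_improvement(m, s**2, fmax)
        assert ours == pytest.approx(oracle, abs=1e-8)

    def test_nonnegative_in_both_forms(self, rng):
        m = rng.normal(size=200)
        var = rng.uniform(0, 2, size=200)
        for form in ("standard", "paper_literal"):
            assert np.all(expected_improvement(m, var, 0.5, form=form) >= 0)

    def test_paper_literal_substitutes_variance_for_sd(self):
        m, var, fmax = 0.1, 0.25, 0.4
        s = var  # the printed equations use var(x) where the SD belongs
        z = (m - fmax) / s
        expected = (m - fmax) * norm.cdf(z) + s * norm.pdf(z)
        assert expected_improvement(m, var, fmax, form="paper_literal") == pytest.approx(
            expected, abs=1e-12
        )


class TestProposeNext:
    def test_unique_maximum_is_returned(self, study2):
        p = KernelParams(1.0, (2.0, 2.0), 0.01)
        m = GpModel(params=p, X=[[7, 13]], y=[1.0])
        # the only observation is the incumbent; EI peaks near it
        pick = propose_next(m, study2, rng=np.random.default_rng(0))
        assert study2.contains(pick)

    def test_uniform_tie_break_over_flat_ei(self, study2):
        # no observations: EI is constant over the grid, so proposals
        # should be uniform (chi-square over 361 cells)
        p = KernelParams(1.0, (3.0, 3.0), 0.1)
        m = GpModel(params=p)
        rng = np.random.default_rng(42)
        counts = np.zeros(study2.n_positions)
        pos_index = {tuple(c): i for i, c in enumerate(map(tuple, study2.positions()))}
        n = 10_000
        for _ in range(n):
            counts[pos_index[propose_next(m, study2, f_max=0.0, rng=rng)]] += 1
        expected = n / study2.n_positions
        chi2 = np.sum((counts - expected) ** 2 / expected)
        from scipy.stats import chi2 as chi2_dist

        assert chi2_dist.sf(chi2, study2.n_positions - 1) > 0.01


class TestRunBayesopt:
    def test_burn_in_only_run(self, study2, params):
        run = run_bayesopt(lambda c: 0.1, study2, params, n_burn=5, n_obs=5, seed=1)
        assert len(run.proposals) == 5
        assert len(set(run.proposals)) == 5  # without replacement

    def test_default_budget_samples_5_26_percent(self, study2, params):
        run = run_bayesopt(lambda c: 0.0, study2, params, seed=0)
        assert len(run.proposals) == 19
        assert 100 * len(run.proposals) / study2.n_positions == pytest.approx(5.26, abs=0.005)

    def test_noiseless_center_surface_found(self, study2, truth_surface):
        p = KernelParams(1.0, (4.0, 4.0), 1e-4)
        hits = 0
        for seed in range(10):
            run = run_bayesopt(
                lambda c: truth_surface.value_at(c), study2, p, seed=seed
            )
            mean, _ = gp_predict(run.model, study2.positions())
            best = study2.positions()[int(np.argmax(mean))]
            if np.linalg.norm(best - np.array(truth_surface.optimum)) <= 2:
                hits += 1
        assert hits >= 9

    def test_long_noiseless_run_maps_whole_surface(self, study2, truth_surface):
        from boldopt.simloop import spatial_correlation

        p = KernelParams(1.0, (4.0, 4.0), 1e-4)
        run = run_bayesopt(
            lambda c: truth_surface.value_at(c), study2, p, n_obs=100, seed=3
        )
        mean, _ = gp_predict(run.model, study2.positions())
        assert spatial_correlation(mean, truth_surface.values) > 0.95

    def test_same_seed_reproduces(self, study2, truth_surface, params):
        runs = []
        for _ in range(2):
            rng = np.random.default_rng(5)
            runs.append(
                run_bayesopt(
                    lambda c: truth_surface.value_at(c) + rng.normal(0, 0.5),
                    study2, params, seed=9,
                )
            )
        assert runs[0].proposals == runs[1].proposals
        assert np.array_equal(runs[0].model.y, runs[1].model.y)

    def test_n_burn_cannot_exceed_n_obs(self, study2, params):
        with pytest.raises(ValueError):
            run_bayesopt(lambda c: 0.0, study2, params, n_burn=20, n_obs=19)
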