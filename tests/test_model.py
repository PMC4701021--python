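"""Unit and property tests for the VBFA core: E-step, M-step, free energy,
fitting, and the exact marginal likelihood."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad
from scipy.linalg import subspace_angles
from scipy.optimize import minimize
from scipy.stats import multivariate_normal

from vbfa_bci import (
    FactorModel,
    FitConfig,
    e_step,
    fit,
    free_energy,
    load_model,
    log_likelihood,
    m_step,
    save_model,
)


def _random_model(rng, K, L, lam_scale=1.0):
    return FactorModel(
        A=rng.standard_normal((K, L)),
        lambda_prec=lam_scale * (0.5 + rng.random(K)),
        alpha_prec=0.5 + rng.random(L),
    )


# ---------------------------------------------------------------------------
# E-step
# ---------------------------------------------------------------------------

class TestEStep:
    def test_single_factor_hand_example(self):
        # A = e1, unit precisions, y = (4, 7): Gamma = 1 + 1 = 2, x = 4/2.
        model = FactorModel(A=[[1.0], [0.0]], lambda_prec=[1.0, 1.0], alpha_prec=[1.0])
        stats = e_step(np.array([[4.0], [7.0]]), model)
        assert stats.gamma_prec == pytest.approx(np.array([[2.0]]))
        assert stats.x_mean == pytest.approx(np.array([[2.0]]))

    def test_zero_mixing_matrix_gives_prior_posterior(self, rng):
        model = FactorModel(
            A=np.zeros((4, 2)), lambda_prec=np.ones(4), alpha_prec=np.ones(2)
        )
        Y = rng.standard_normal((4, 7))
        stats = e_step(Y, model)
        np.testing.assert_allclose(stats.gamma_prec, np.eye(2))
        np.testing.assert_allclose(stats.x_mean, 0.0)
        np.testing.assert_allclose(stats.R_yx, 0.0)

    def test_posterior_mean_minimizes_regularized_quadratic(self, rng):
        """x_bar must minimize (y - Ax)' diag(lam) (y - Ax) + x'x; cross-check
        against a generic numerical optimizer."""
        K, L = 5, 2
        model = _random_model(rng, K, L)
        y = rng.standard_normal(K)
        stats = e_step(y[:, None], model)

        def objective(x):
            r = y - model.A @ x
            return r @ (model.lambda_prec * r) + x @ x

        res = minimize(objective, np.zeros(L), method="BFGS", tol=1e-12)
        np.testing.assert_allclose(stats.x_mean[:, 0], res.x, atol=1e-6)

    def test_sufficient_statistics_definitions(self, rng):
        K, L, N = 6, 3, 40
        model = _random_model(rng, K, L)
        Y = rng.standard_normal((K, N))
        stats = e_step(Y, model)
        np.testing.assert_allclose(stats.R_yy, np.sum(Y * Y, axis=1))
        np.testing.assert_allclose(stats.R_yx, Y @ stats.x_mean.T)
        np.testing.assert_allclose(
            stats.R_xx, stats.x_mean @ stats.x_mean.T + N * stats.gamma_cov
        )
        np.testing.assert_allclose(
            stats.gamma_cov @ stats.gamma_prec, np.eye(L), atol=1e-8
        )
        # R_xx is symmetric PSD
        assert np.all(np.linalg.eigvalsh(stats.R_xx) >= -1e-10)

    def test_dimension_and_finiteness_errors(self, rng):
        model = _random_model(rng, 4, 2)
        with pytest.raises(ValueError, match="channels"):
            e_step(rng.standard_normal((3, 5)), model)
        bad = rng.standard_normal((4, 5))
        bad[0, 0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            e_step(bad, model)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(seed=st.integers(0, 10_000), k=st.integers(1, 8), l=st.integers(1, 5))
    def test_gamma_is_spd_with_unit_lower_bound(self, seed, k, l):
        """Gamma = A' diag(lam) A + I: its spectrum never dips below 1."""
        r = np.random.default_rng(seed)
        model = _random_model(r, k, l, lam_scale=r.uniform(0.1, 10))
        stats = e_step(r.standard_normal((k, 3)), model)
        assert np.linalg.eigvalsh(stats.gamma_prec).min() >= 1 - 1e-10


# ---------------------------------------------------------------------------
# M-step
# ---------------------------------------------------------------------------

class TestMStep:
    def test_zero_correlation_gives_zero_mixing(self, rng):
        K, L, N = 4, 2, 10
        model = _random_model(rng, K, L)
        Y = np.zeros((K, N))
        stats = e_step(Y, model)
        new = m_step(stats, model, FitConfig(n_factors=L))
        np.testing.assert_allclose(new.A, 0.0)

    def test_hand_arithmetic_single_channel(self):
        """K=1, L=1, N=2, y=(1,-1), x_bar=(1,-1), vanishing posterior
        covariance and alpha: the residual is exactly zero, so the noise
        variance hits the configured floor."""
        from vbfa_bci.model import PosteriorStats

        model = FactorModel(A=[[0.5]], lambda_prec=[1.0], alpha_prec=[1e-12])
        stats = PosteriorStats(
            x_mean=np.array([[1.0, -1.0]]),
            gamma_prec=np.array([[1e12]]),
            gamma_cov=np.array([[1e-12]]),
            R_yx=np.array([[2.0]]),
            R_xx=np.array([[2.0]]),
            R_yy=np.array([2.0]),
            n_samples=2,
        )
        config = FitConfig(n_factors=1, noise_denominator="n")
        new = m_step(stats, model, config)
        assert new.A == pytest.approx(np.array([[1.0]]), rel=1e-9)
        floor = config.precision_floor * (2.0 / 2)  # mean data variance = 1
        assert 1.0 / new.lambda_prec[0] == pytest.approx(floor, rel=1e-6)

    def test_noise_update_reduces_to_sample_variance(self):
        """With a zero mixing matrix the ML noise update is the per-channel
        sample variance (1/N mode)."""
        from vbfa_bci.model import PosteriorStats

        model = FactorModel(A=np.zeros((2, 1)), lambda_prec=[1.0, 1.0], alpha_prec=[1.0])
        stats = PosteriorStats(
            x_mean=np.zeros((1, 2)),
            gamma_prec=np.eye(1),
            gamma_cov=np.eye(1),
            R_yx=np.zeros((2, 1)),
            R_xx=2 * np.eye(1),
            R_yy=np.array([2.0, 2.0]),
            n_samples=2,
        )
        new = m_step(stats, model, FitConfig(n_factors=1, noise_denominator="n"))
        np.testing.assert_allclose(1.0 / new.lambda_prec, [1.0, 1.0])
        # the variational 1/(N+L) mode shares the same sufficient statistics
        new_nl = m_step(stats, model, FitConfig(n_factors=1, noise_denominator="n_plus_l"))
        np.testing.assert_allclose(1.0 / new_nl.lambda_prec, [2.0 / 3, 2.0 / 3])

    def test_zero_samples_rejected(self, rng):
        model = _random_model(rng, 3, 1)
        stats = e_step(rng.standard_normal((3, 4)), model)
        stats.n_samples = 0
        with pytest.raises(ValueError, match="zero samples"):
            m_step(stats, model, FitConfig(n_factors=1))


# ---------------------------------------------------------------------------
# free energy
# ---------------------------------------------------------------------------

class TestFreeEnergy:
    def test_zero_data_identity_model_gives_zero(self):
        K, L, N = 3, 2, 5
        model = FactorModel(A=np.zeros((K, L)), lambda_prec=np.ones(K), alpha_prec=np.ones(L))
        Y = np.zeros((K, N))
        stats = e_step(Y, model)
        assert free_energy(Y, model, stats) == pytest.approx(0.0, abs=1e-10)

    def test_doubling_data_decreases_objective(self, rng):
        K, L, N = 6, 2, 50
        model = _random_model(rng, K, L)
        Y = rng.standard_normal((K, N))
        f1 = free_energy(Y, model, e_step(Y, model))
        f2 = free_energy(2 * Y, model, e_step(2 * Y, model))
        assert f2 < f1

    @pytest.mark.parametrize("denominator", ["n", "n_plus_l"])
    def test_monotone_over_em_sweeps_many_seeds(self, denominator):
        """The free-energy trace never decreases (relative tolerance 1e-8)
        across EM sweeps, for 20 random problems and both noise updates."""
        for seed in range(20):
            r = np.random.default_rng(seed)
            K, L, N = 8, 2, 500
            A = r.standard_normal((K, L))
            Y = A @ r.standard_normal((L, N)) + 0.5 * r.standard_normal((K, N))
            cfg = FitConfig(n_factors=3, noise_denominator=denominator, max_iter=60)
            trace = fit(Y, config=cfg).fit_info.free_energy_trace
            diffs = np.diff(trace)
            assert np.all(diffs >= -1e-8 * np.abs(trace[1:])), f"seed {seed}"


# ---------------------------------------------------------------------------
# fit
# ---------------------------------------------------------------------------

class TestFit:
    def test_recovers_planted_subspace_and_noise_level(self):
        """On data simulated from the model at SNR 10, the fitted mixing
        matrix spans the true subspace (angle < 5 degrees) and the fitted
        noise variances agree with the truth in the median."""
        rng = np.random.default_rng(7)
        K, L, N = 10, 3, 2000
        A = rng.standard_normal((K, L))
        A /= np.linalg.norm(A, axis=0)
        noise_var = L / (K * 10)
        Y = A @ rng.standard_normal((L, N)) + np.sqrt(noise_var) * rng.standard_normal((K, N))
        model = fit(Y, n_factors=L)
        assert model.fit_info.converged
        angle = np.degrees(subspace_angles(model.A, A)).max()
        assert angle < 5.0
        rel_err = np.abs(1.0 / model.lambda_prec - noise_var) / noise_var
        assert np.median(rel_err) < 0.15

    def test_subspace_angle_shrinks_with_sample_size(self):
        """Parameter recovery sharpens as N grows (median over seeds)."""
        angles = {}
        for N in (200, 1000, 5000):
            per_seed = []
            for seed in range(5):
                r = np.random.default_rng(seed)
                K, L = 10, 2
                A = r.standard_normal((K, L))
                A /= np.linalg.norm(A, axis=0)
                Y = A @ r.standard_normal((L, N)) + 0.1 * r.standard_normal((K, N))
                m = fit(Y, n_factors=L)
                per_seed.append(np.degrees(subspace_angles(m.A, A)).max())
            angles[N] = np.median(per_seed)
        assert angles[200] >= angles[1000] >= angles[5000]

    def test_ard_prunes_factor_on_pure_noise(self):
        """Unit-variance noise with one fitted factor: the noise variance is
        recovered and the ARD prior shrinks the mixing column."""
        rng = np.random.default_rng(3)
        Y = rng.standard_normal((6, 5000))
        model = fit(Y, n_factors=1, config=FitConfig(n_factors=1, max_iter=500))
        np.testing.assert_allclose(1.0 / model.lambda_prec, 1.0, rtol=0.1)
        col_norm = np.linalg.norm(model.A[:, 0])
        # initial column norm is O(largest singular value) ~ O(1)
        assert col_norm < 0.2
        assert model.alpha_prec[0] > 10.0

    def test_deterministic_for_fixed_seed_and_input(self, rng, small_config):
        Y = rng.standard_normal((6, 100))
        m1 = fit(Y.copy(), config=small_config)
        m2 = fit(Y.copy(), config=small_config)
        assert np.array_equal(m1.A, m2.A)
        assert np.array_equal(m1.lambda_prec, m2.lambda_prec)
        assert np.array_equal(m1.alpha_prec, m2.alpha_prec)

    def test_channel_permutation_equivariance(self, rng, small_config):
        """Permuting channels of the data permutes the fitted A and lambda."""
        Y = rng.standard_normal((5, 2)) @ rng.standard_normal((2, 400))
        Y += 0.3 * rng.standard_normal((5, 400))
        perm = np.array([3, 0, 4, 1, 2])
        m = fit(Y, config=small_config)
        mp = fit(Y[perm], config=small_config)
        np.testing.assert_allclose(mp.A, m.A[perm], rtol=1e-6, atol=1e-10)
        np.testing.assert_allclose(mp.lambda_prec, m.lambda_prec[perm], rtol=1e-6)

    def test_rank_bound_enforced(self, rng):
        Y = rng.standard_normal((4, 10))
        with pytest.raises(ValueError, match="n_factors"):
            fit(Y, n_factors=5)

    def test_random_init_mode_also_converges(self, rng):
        Y = rng.standard_normal((6, 3)) @ rng.standard_normal((3, 500))
        Y += 0.2 * rng.standard_normal((6, 500))
        cfg = FitConfig(n_factors=3, init="random", seed=11, max_iter=300)
        model = fit(Y, config=cfg)
        trace = model.fit_info.free_energy_trace
        assert np.all(np.diff(trace) >= -1e-8 * np.abs(trace[1:]))


# ---------------------------------------------------------------------------
# marginal likelihood
# ---------------------------------------------------------------------------

class TestLogLikelihood:
    def test_standard_normal_closed_form(self):
        model = FactorModel(A=np.zeros((2, 1)), lambda_prec=[1.0, 1.0], alpha_prec=[1.0])
        assert log_likelihood(np.zeros((2, 1)), model) == pytest.approx(
            -np.log(2 * np.pi), abs=1e-6
        )

    def test_rank_one_closed_form(self):
        # Sigma = A A' + lam^-1 = 1 + 1 = 2
        model = FactorModel(A=[[1.0]], lambda_prec=[1.0], alpha_prec=[1.0])
        assert log_likelihood(np.zeros((1, 1)), model) == pytest.approx(
            -0.5 * np.log(2 * np.pi * 2.0), abs=1e-6
        )

    def test_matches_adaptive_quadrature(self, rng):
        """K=2, L=1: the marginal integral over the scalar factor evaluated
        by adaptive quadrature matches the analytic path to 1e-6."""
        model = _random_model(rng, 2, 1)
        y = rng.standard_normal(2)

        def integrand(x):
            r = y - model.A[:, 0] * x
            lik = np.prod(
                np.sqrt(model.lambda_prec / (2 * np.pi))
                * np.exp(-0.5 * model.lambda_prec * r**2)
            )
            return lik * np.exp(-0.5 * x * x) / np.sqrt(2 * np.pi)

        val, err = quad(integrand, -12, 12, epsabs=1e-13)
        assert log_likelihood(y[:, None], model) == pytest.approx(np.log(val), abs=1e-6)

    def test_low_rank_identity_equals_direct_evaluation(self):
        """The L-dimensional evaluation equals a direct K-dimensional
        N(0, AA' + diag(lam)^-1) log-density to 1e-8."""
        for seed in range(10):
            r = np.random.default_rng(seed)
            K, L, N = 7, 3, 4
            model = _random_model(r, K, L, lam_scale=r.uniform(0.2, 5))
            Y = r.standard_normal((K, N))
            sigma = model.A @ model.A.T + np.diag(1.0 / model.lambda_prec)
            direct = multivariate_normal.logpdf(Y.T, mean=np.zeros(K), cov=sigma).sum()
            assert log_likelihood(Y, model) == pytest.approx(direct, abs=1e-8)

    def test_dimension_mismatch_rejected(self, rng):
        model = _random_model(rng, 4, 2)
        with pytest.raises(ValueError, match="channels"):
            log_likelihood(rng.standard_normal((3, 5)), model)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def test_model_round_trip_is_bit_exact(tmp_path, rng, small_config):
    Y = rng.standard_normal((6, 200))
    model = fit(Y, config=small_config)
    save_model(model, tmp_path / "m", config=small_config)
    loaded = load_model(tmp_path / "m")
    assert np.array_equal(loaded.A, model.A)
    assert np.array_equal(loaded.lambda_prec, model.lambda_prec)
    assert np.array_equal(loaded.alpha_prec, model.alpha_prec)
    assert loaded.fit_info.n_iter == model.fit_info.n_iter
    assert loaded.fit_info.free_energy == model.fit_info.free_energy
    np.testing.assert_array_equal(
        loaded.fit_info.free_energy_trace, model.fit_info.free_energy_trace
    )


def test_invalid_precisions_rejected():
    with pytest.raises(ValueError, match="positive"):
        FactorModel(A=np.ones((2, 1)), lambda_prec=[1.0, -1.0], alpha_prec=[1.0])
    with pytest.raises(ValueError, match="positive"):
        FactorModel(A=np.ones((2, 1)), lambda_prec=[1.0, 1.0], alpha_prec=[0.0])
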