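"""Unit tests for the splitting integrators, the OU transition covariance,
trajectory drivers and the convergence-order machinery."""

import math

import numpy as np
import pytest
from scipy.signal import welch

from jrnmm import (
    InputSpec,
    ModelParameters,
    displacement,
    estimate_ms_order,
    kernel_blocks,
    ou_step_covariance,
    sample_ensemble,
    simulate,
    step_em,
    step_ou,
    step_strang,
    step_wiener,
)
from jrnmm.integrators import _ou_increments_from_fine, _run_coupled


@pytest.fixture(scope="module")
def linear_params():
    """Parameters with (numerically) no sigmoid coupling: the SDE is linear."""
    return ModelParameters.from_C(135.0, nu_max=1e-300)


class TestOUStepCovariance:
    def test_zero_noise_gives_zero_matrix(self, params):
        cov = ou_step_covariance(1e-3, params, InputSpec()).cov
        np.testing.assert_array_equal(cov, np.zeros((6, 6)))

    def test_closed_form_matches_ode_integration(self, params, alpha_inputs):
        a = ou_step_covariance(2e-3, params, alpha_inputs, closed_form=True).cov
        b = ou_step_covariance(2e-3, params, alpha_inputs, closed_form=False).cov
        assert np.abs(a - b).max() / np.abs(a).max() < 1e-8

    def test_long_time_limit_is_stationary_covariance(self, params, alpha_inputs):
        cov = ou_step_covariance(5.0, params, alpha_inputs).cov
        sigma = alpha_inputs.sigma_diag
        expected = 0.25 * params.gamma ** (-3.0) * sigma**2
        np.testing.assert_allclose(np.diag(cov)[:3], expected, rtol=1e-10)

    @pytest.mark.parametrize("dt", [1e-5, 1e-3, 1e-1, 1.0])
    def test_psd_and_factor_roundtrip(self, dt, params, alpha_inputs):
        c = ou_step_covariance(dt, params, alpha_inputs)
        w = np.linalg.eigvalsh(c.cov)
        assert w.min() >= -1e-12 * np.abs(c.cov).max()
        L = c.factor()
        assert np.abs(L @ L.T - c.cov).max() <= 1e-10 * max(np.abs(c.cov).max(), 1.0)

    def test_rejects_nonpositive_step(self, params, alpha_inputs):
        with pytest.raises(ValueError):
            ou_step_covariance(0.0, params, alpha_inputs)


class TestOneStepMaps:
    def test_pure_linear_flow_is_matrix_exponential(self, linear_params):
        # no noise, no displacement: every splitting step is exactly e^{M dt}
        ins = InputSpec()
        x = np.array([1.0, -2.0, 0.5, 10.0, 0.0, -3.0])
        E = kernel_blocks(2e-3, linear_params).expm
        for step in (step_ou, step_wiener, step_strang):
            out = step(x, 0.0, 2e-3, None, params=linear_params, inputs=ins)
            np.testing.assert_allclose(out, E @ x, rtol=1e-12)

    def test_deterministic_lie_trotter_composition(self, params, quiet_inputs, rng):
        # hand-compose the two sub-flows: kick then linear flow
        x = rng.normal(0, 5, size=6)
        dt = 1e-3
        g = displacement(0.0, x[:3], params, quiet_inputs)
        kicked = x.copy()
        kicked[3:] += dt * g.gii + g.gi * dt
        expected = kernel_blocks(dt, params).expm @ kicked
        for step in (step_ou, step_wiener):
            out = step(x, 0.0, dt, None, params=params, inputs=quiet_inputs)
            np.testing.assert_allclose(out, expected, rtol=1e-12)

    def test_commuted_composition_swaps_flow_order(self, params, quiet_inputs, rng):
        x = rng.normal(0, 5, size=6)
        dt = 1e-3
        flowed = kernel_blocks(dt, params).expm @ x
        g = displacement(0.0, flowed[:3], params, quiet_inputs)
        expected = flowed.copy()
        expected[3:] += dt * g.gii + g.gi * dt
        out = step_wiener(x, 0.0, dt, None, params=params, inputs=quiet_inputs, commute=True)
        np.testing.assert_allclose(out, expected, rtol=1e-12)

    def test_wiener_equals_ou_without_noise(self, params, quiet_inputs, rng):
        x = rng.normal(0, 5, size=6)
        a = step_ou(x, 0.0, 1e-3, None, params=params, inputs=quiet_inputs)
        b = step_wiener(x, 0.0, 1e-3, None, params=params, inputs=quiet_inputs)
        np.testing.assert_allclose(a, b, rtol=1e-14)

    def test_ou_step_distribution(self, params, alpha_inputs, rng):
        # Monte-Carlo moments of a single step from the origin
        n, dt = 200_000, 2e-3
        z = rng.standard_normal((n, 6))
        out = step_ou(np.zeros((n, 6)), 0.0, dt, z, params=params, inputs=alpha_inputs)
        G0 = displacement(0.0, np.zeros(3), params, alpha_inputs).total
        mean_th = kernel_blocks(dt, params).expm @ np.concatenate([np.zeros(3), dt * G0])
        cov_th = ou_step_covariance(dt, params, alpha_inputs).cov
        sd = np.sqrt(np.diag(cov_th) / n)
        assert np.all(np.abs(out.mean(axis=0) - mean_th) < 5 * sd)
        cov_emp = np.cov(out.T)
        assert np.abs(cov_emp - cov_th).max() < 0.02 * np.abs(cov_th).max()

    def test_wiener_kick_covariance_is_dt_sigma_squared(self, params, alpha_inputs):
        # the stochastic kick is linear in the draws with coefficient Sigma sqrt(dt)
        dt = 1e-3
        base = step_wiener(np.zeros(6), 0.0, dt, np.zeros(3), params=params, inputs=alpha_inputs)
        E = kernel_blocks(dt, params).expm
        sigma = alpha_inputs.sigma_diag
        for k in range(3):
            e = np.zeros(3)
            e[k] = 1.0
            out = step_wiener(np.zeros(6), 0.0, dt, e, params=params, inputs=alpha_inputs)
            effect = out - base
            expected = E @ np.concatenate([np.zeros(3), math.sqrt(dt) * sigma * e])
            np.testing.assert_allclose(effect, expected, rtol=1e-10, atol=1e-12)

    def test_strang_one_step_distribution(self, params, alpha_inputs, rng):
        # one Strang step from a fixed state is Gaussian with the composed
        # sub-flow mean and covariance
        n, dt = 200_000, 2e-3
        x = np.array([0.05, 5.0, 2.0, 1.0, -1.0, 0.5])
        z = rng.standard_normal((n, 3))
        out = step_strang(np.tile(x, (n, 1)), 0.0, dt, z, params=params, inputs=alpha_inputs)
        Eh = kernel_blocks(dt / 2, params).expm
        mid = Eh @ x
        g = displacement(0.0, mid[:3], params, alpha_inputs)
        mid_kicked = mid.copy()
        mid_kicked[3:] += dt * g.gii + g.gi * dt
        mean_th = Eh @ mid_kicked
        S = np.zeros((6, 3))
        S[3:, :] = np.diag(alpha_inputs.sigma_diag)
        A = Eh @ S
        cov_th = dt * (A @ A.T)
        sd = np.sqrt(np.diag(cov_th) / n) + 1e-12
        assert np.all(np.abs(out.mean(axis=0) - mean_th) < 5 * sd)
        cov_emp = np.cov(out.T)
        assert np.abs(cov_emp - cov_th).max() < 0.02 * np.abs(cov_th).max()

    def test_em_identity_without_drift_and_noise(self, linear_params):
        # zero state is a fixed point of the (numerically) linear drift
        ins = InputSpec()
        out = step_em(np.zeros(6), 0.0, 1e-3, None, params=linear_params, inputs=ins)
        np.testing.assert_allclose(out, np.zeros(6), atol=1e-290)

    def test_em_linear_mean_is_first_order_taylor(self, linear_params, rng):
        from jrnmm import drift_matrix

        ins = InputSpec()
        x = rng.normal(size=6)
        dt = 1e-3
        out = step_em(x, 0.0, dt, None, params=linear_params, inputs=ins)
        M = drift_matrix(linear_params)
        np.testing.assert_allclose(out, (np.eye(6) + dt * M) @ x, rtol=1e-12)
        exact = kernel_blocks(dt, linear_params).expm @ x
        diff = np.linalg.norm(out - exact)
        assert 0 < diff < (np.linalg.norm(M @ M @ x) * dt**2)


class TestSimulate:
    def test_same_seed_bit_identical(self, params, alpha_inputs):
        a = simulate("strang", np.zeros(6), 0.2, 1e-3, 42, params, alpha_inputs)
        b = simulate("strang", np.zeros(6), 0.2, 1e-3, 42, params, alpha_inputs)
        np.testing.assert_array_equal(a.states, b.states)

    def test_unknown_scheme_rejected(self, params, alpha_inputs):
        with pytest.raises(ValueError, match="unknown scheme"):
            simulate("rk4", np.zeros(6), 0.1, 1e-3, 0, params, alpha_inputs)

    def test_grid_is_equidistant_and_consistent(self, params, alpha_inputs):
        traj = simulate("ou", np.zeros(6), 0.5, 1e-3, 3, params, alpha_inputs)
        spac = np.diff(traj.t)
        assert np.abs(spac - traj.dt).max() < 1e-12
        assert len(traj.t) - 1 == round(0.5 / 1e-3)

    def test_alpha_band_spectral_peak(self, params, alpha_inputs):
        traj = simulate("strang", np.zeros(6), 10.0, 1e-3, 5, params, alpha_inputs)
        y = traj.y[2000:]
        f, pxx = welch(y - y.mean(), fs=1.0 / traj.dt, nperseg=4096)
        assert 8.0 <= f[np.argmax(pxx)] <= 12.0

    def test_deterministic_run_reaches_limit_cycle(self, params, quiet_inputs):
        traj = simulate("strang", np.zeros(6), 5.0, 1e-3, None, params, quiet_inputs)
        tail = traj.y[3000:]
        # oscillation with positive, bounded amplitude after the transient
        assert tail.min() > 0
        amplitude = tail.max() - tail.min()
        assert 1.0 < amplitude < 20.0

    def test_ensemble_records_requested_times_only(self, params, alpha_inputs):
        times, states = sample_ensemble(
            "wiener", np.zeros(6), 0.5, 1e-3, 7, 1, params, alpha_inputs,
            record_times=[0.1, 0.3, 0.5],
        )
        np.testing.assert_allclose(times, [0.1, 0.3, 0.5])
        assert states.shape == (7, 3, 6)

    def test_off_grid_record_time_rejected(self, params, alpha_inputs):
        with pytest.raises(ValueError, match="grid"):
            sample_ensemble(
                "wiener", np.zeros(6), 0.5, 1e-3, 2, 1, params, alpha_inputs,
                record_times=[0.10005],
            )


class TestConvergenceMachinery:
    def test_brownian_aggregation_is_exact_sum(self, rng):
        fine = rng.normal(size=(4, 12, 3))
        coarse = fine.reshape(4, 3, 4, 3).sum(axis=2)
        np.testing.assert_allclose(coarse[:, 0, :], fine[:, :4, :].sum(axis=1))

    def test_scheme_against_itself_has_zero_error(self, params, alpha_inputs, rng):
        # identical increments through the coupled runner -> identical endpoints
        n, steps, dt = 8, 50, 1e-3
        dW = math.sqrt(dt) * rng.standard_normal((n, steps, 3))
        x0 = np.zeros((n, 6))
        a = _run_coupled("wiener", x0, dt, steps, params, alpha_inputs, dW=dW)
        b = _run_coupled("wiener", x0, dt, steps, params, alpha_inputs, dW=dW)
        np.testing.assert_array_equal(a, b)

    def test_ou_increment_reconstruction_covariance(self, params, alpha_inputs, rng):
        # the Riemann-sum OU increments converge to the exact covariance
        dt, m = 1e-3, 64
        delta = dt / m
        fine = math.sqrt(delta) * rng.standard_normal((20_000, m, 3))
        xi = _ou_increments_from_fine(fine, m, delta, params, alpha_inputs.sigma_diag)
        cov_emp = np.cov(xi[:, 0, :].T)
        cov_th = ou_step_covariance(dt, params, alpha_inputs).cov
        assert np.abs(cov_emp - cov_th).max() < 0.05 * np.abs(cov_th).max()

    def test_requires_three_dyadic_steps(self, params, alpha_inputs):
        with pytest.raises(ValueError, match="three"):
            estimate_ms_order("wiener", params, alpha_inputs, dt_list=[2e-3, 1e-3])
        with pytest.raises(ValueError, match="dyadic"):
            estimate_ms_order("wiener", params, alpha_inputs, dt_list=[3e-3, 2e-3, 1e-3])

    def test_deterministic_orders_small_scale(self, params, quiet_inputs):
        # Strang is second order, Lie-Trotter first order on the noiseless model
        strang = estimate_ms_order(
            "strang", params, quiet_inputs, T=0.5,
            dt_list=[2e-3, 1e-3, 5e-4, 2.5e-4], n_paths=1, seed=3,
        )
        lt = estimate_ms_order(
            "wiener", params, quiet_inputs, T=0.5,
            dt_list=[2e-3, 1e-3, 5e-4, 2.5e-4], n_paths=1, seed=3,
        )
        assert 1.75 <= strang.slope <= 2.25
        assert 0.75 <= lt.slope <= 1.25

    def test_stochastic_order_reseeding_stability(self, params, alpha_inputs):
        # estimated order is seed-robust at moderate path counts
        slopes = [
            estimate_ms_order(
                "wiener", params, alpha_inputs, T=0.5,
                dt_list=[4e-3, 2e-3, 1e-3], n_paths=200, seed=s,
            ).slope
            for s in (1, 2)
        ]
        assert abs(slopes[0] - slopes[1]) < 0.1
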