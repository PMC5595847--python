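"""Field dynamics: nonlinearity, convolution oracle, solvers, equilibria."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ringmt import (KernelParams, NetworkParams, RingGrid, StimulusSpec,
                    build_kernel, energy, euler_maruyama, find_steady_state,
                    integrate, jacobian, make_input, rhs, sigmoid,
                    sigmoid_prime)
from ringmt.dynamics import DivergenceError, newton_polish
from ringmt.stimulus import InputProfile


def _profile(grid, values, ps=120.0):
    return InputProfile(spec=StimulusSpec(ps=ps, pw=10.0), grid=grid,
                        values=values)


class TestSigmoid:
    def test_zero_at_rest(self):
        assert sigmoid(0.0) == pytest.approx(0.0, abs=1e-15)

    def test_saturation_level(self):
        # limit 1 - 1/(1+e^3) = 0.95257
        assert sigmoid(1e3) == pytest.approx(0.95257, abs=1e-5)

    def test_direct_evaluation_at_half(self):
        # 1/(1+e^-5) - 1/(1+e^3) = 0.94588
        assert sigmoid(0.5, mu=16.0, th=3.0) == pytest.approx(0.94588, abs=1e-5)

    def test_overflow_safe(self):
        assert np.isfinite(sigmoid(np.array([-1e6, 1e6]))).all()

    @given(st.floats(min_value=-50, max_value=50))
    @settings(max_examples=50, deadline=None)
    def test_bounded_and_nondecreasing(self, u):
        lo = -1.0 / (1.0 + np.exp(3.0))
        assert lo - 1e-12 <= sigmoid(u) <= 1.0
        assert sigmoid(u + 1e-3) >= sigmoid(u)
        if abs(u) < 2.0:  # strictly increasing away from saturation
            assert sigmoid(u + 1e-3) > sigmoid(u)

    def test_derivative_matches_finite_differences(self):
        u = np.linspace(-0.5, 0.8, 11)
        h = 1e-6
        fd = (sigmoid(u + h) - sigmoid(u - h)) / (2 * h)
        assert np.allclose(sigmoid_prime(u), fd, atol=1e-5)


class TestRhs:
    def test_rest_state_is_equilibrium(self, grid404, kernel404):
        inp = _profile(grid404, np.zeros(grid404.n))
        du = rhs(np.zeros(grid404.n), kernel404, inp, NetworkParams())
        assert np.allclose(du, 0.0, atol=1e-15)

    def test_only_input_term_at_rest(self, grid404, kernel404):
        rng = np.random.default_rng(1)
        vals = rng.uniform(0.0, 1.0, grid404.n)
        inp = _profile(grid404, vals)
        p = NetworkParams(tau_p=5.0)
        du = rhs(np.zeros(grid404.n), kernel404, inp, p)
        assert np.allclose(du, p.kappa_i * vals / p.tau_p, atol=1e-14)

    def test_convolution_matches_double_loop_quadrature(self, grid202,
                                                        kernel202):
        rng = np.random.default_rng(2)
        u = rng.normal(0.0, 0.3, grid202.n)
        inp = _profile(grid202, np.zeros(grid202.n))
        p = NetworkParams()
        fast = rhs(u, kernel202, inp, p)
        # independent O(N^2) oracle
        s = sigmoid(u, p.mu, p.th)
        n, dth = grid202.n, grid202.dtheta
        slow = np.empty(n)
        col = np.roll(kernel202.values, -(n // 2))
        for j in range(n):
            acc = 0.0
            for k in range(n):
                acc += col[(j - k) % n] * s[k]
            slow[j] = (-u[j] + acc * dth) / p.tau_p
        assert np.allclose(fast, slow, atol=1e-10)

    def test_rotation_equivariance(self, grid404, kernel404):
        rng = np.random.default_rng(3)
        u = rng.normal(0.0, 0.3, grid404.n)
        inp = make_input(StimulusSpec(ps=100.0, pw=10.0), grid404)
        p = NetworkParams()
        k = 37
        du = rhs(u, kernel404, inp, p)
        du_rot = rhs(np.roll(u, k), kernel404,
                     _profile(grid404, np.roll(inp.values, k)), p)
        assert np.allclose(np.roll(du, k), du_rot, atol=1e-8)

    def test_mirror_equivariance_for_symmetric_input(self, grid404, kernel404):
        refl = np.array([grid404.index_of(-t) for t in grid404.theta])
        rng = np.random.default_rng(4)
        u = rng.normal(0.0, 0.3, grid404.n)
        inp = make_input(StimulusSpec(va_direction=0.0, ps=120.0, pw=10.0,
                                      rel_strength=1.0), grid404)
        p = NetworkParams()
        assert np.allclose(rhs(u, kernel404, inp, p)[refl],
                           rhs(u[refl], kernel404, inp, p), atol=1e-8)

    def test_grid_mismatch_raises(self, grid404, kernel202):
        inp = _profile(grid404, np.zeros(grid404.n))
        with pytest.raises(ValueError):
            rhs(np.zeros(grid404.n), kernel202, inp, NetworkParams())


class TestJacobian:
    def test_matches_central_finite_differences(self):
        grid = RingGrid(60)
        kernel = build_kernel(KernelParams(alpha=0.2, beta=-5.0), grid)
        inp = _profile(grid, np.zeros(grid.n))
        p = NetworkParams()
        rng = np.random.default_rng(5)
        u = rng.uniform(-0.1, 0.3, grid.n)
        J = jacobian(u, kernel, p)
        h = 1e-6
        for k in range(0, grid.n, 7):
            e = np.zeros(grid.n)
            e[k] = h
            fd = (rhs(u + e, kernel, inp, p) - rhs(u - e, kernel, inp, p)) / (2 * h)
            assert np.allclose(J[:, k], fd, atol=1e-6)


class TestIntegration:
    def test_zero_input_zero_state_stays_at_rest(self, grid202, kernel202):
        inp = _profile(grid202, np.zeros(grid202.n))
        traj = integrate(np.zeros(grid202.n), kernel202, inp,
                         NetworkParams(), t_end=20.0)
        assert np.allclose(traj.final_state, 0.0, atol=1e-10)

    def test_unidirectional_input_gives_centered_bump(self, grid404,
                                                      kernel404):
        spec = StimulusSpec(va_direction=0.0, pw=10.0, n_components=1)
        inp = make_input(spec, grid404)
        ss = find_steady_state(np.full(grid404.n, 0.05), kernel404, inp,
                               NetworkParams())
        assert ss.converged
        peak = grid404.theta[np.argmax(ss.u_star)]
        assert abs(peak) <= grid404.dtheta
        assert ss.u_star.max() > 0.1

    def test_steady_state_rotation_equivariance(self, grid202, kernel202):
        k = 25
        p = NetworkParams()
        spec = StimulusSpec(va_direction=0.0, pw=10.0, n_components=1)
        inp = make_input(spec, grid202)
        ss0 = find_steady_state(np.full(grid202.n, 0.05), kernel202, inp, p)
        rot = _profile(grid202, np.roll(inp.values, k))
        ss1 = find_steady_state(np.full(grid202.n, 0.05), kernel202, rot, p)
        assert np.allclose(np.roll(ss0.u_star, k), ss1.u_star, atol=1e-8)

    def test_euler_matches_adaptive_solver_without_noise(self, grid202,
                                                         kernel202):
        inp = make_input(StimulusSpec(ps=120.0, pw=10.0), grid202)
        u0 = np.full(grid202.n, 0.05)
        p = NetworkParams(dt=1e-4)
        # endpoint past the ignition transient, where the flow has
        # contracted the accumulated first-order error again
        t_end = 12.0
        em = euler_maruyama(u0, kernel202, inp, p, t_end=t_end,
                            record_every=t_end)
        ref = integrate(u0, kernel202, inp, NetworkParams(), t_end=t_end,
                        record_every=t_end, rtol=1e-12, atol=1e-13)
        assert np.max(np.abs(em.final_state - ref.final_state)) < 1e-6

    def test_stochastic_path_reproducible_for_same_seed(self, grid202,
                                                        kernel202):
        inp = make_input(StimulusSpec(ps=120.0, pw=10.0), grid202)
        u0 = np.full(grid202.n, 0.05)
        p = NetworkParams(noise_eps=0.01)
        a = euler_maruyama(u0, kernel202, inp, p, t_end=10.0,
                           rng=np.random.default_rng(11))
        b = euler_maruyama(u0, kernel202, inp, p, t_end=10.0,
                           rng=np.random.default_rng(11))
        assert np.array_equal(a.final_state, b.final_state)

    def test_divergence_reports_time_and_magnitude(self, grid202, kernel202):
        inp = _profile(grid202, np.zeros(grid202.n))
        with pytest.raises(DivergenceError, match="t="):
            euler_maruyama(np.full(grid202.n, 2e6), kernel202, inp,
                           NetworkParams(), t_end=1.0)

    def test_grid_refinement_stability(self, low_inhibition_params):
        # steady states on the standard and a doubled grid agree after
        # interpolation
        p = NetworkParams()
        states = {}
        for n in (404, 808):
            grid = RingGrid(n)
            kernel = build_kernel(low_inhibition_params, grid)
            inp = make_input(StimulusSpec(va_direction=0.0, pw=10.0,
                                          n_components=1), grid)
            ss = find_steady_state(np.full(grid.n, 0.05), kernel, inp, p)
            states[n] = (grid.theta, ss.u_star)
        th4, u4 = states[404]
        th8, u8 = states[808]
        u8_on_4 = np.interp(th4, th8, u8)
        assert np.max(np.abs(u4 - u8_on_4)) < 1e-4


class TestSteadyStates:
    def test_rest_state_found_from_small_random_start(self, grid202,
                                                      kernel202):
        inp = _profile(grid202, np.zeros(grid202.n))
        rng = np.random.default_rng(6)
        ss = find_steady_state(rng.uniform(0, 0.02, grid202.n), kernel202,
                               inp, NetworkParams())
        assert ss.converged and ss.residual < 1e-9
        assert np.allclose(ss.u_star, 0.0, atol=1e-8)

    def test_residual_contract(self, grid404, kernel404):
        inp = make_input(StimulusSpec(ps=120.0, pw=10.0), grid404)
        ss = find_steady_state(np.full(grid404.n, 0.05), kernel404, inp,
                               NetworkParams())
        assert ss.converged
        assert ss.residual < 1e-9
        du = rhs(ss.u_star, kernel404, inp, NetworkParams())
        assert np.max(np.abs(du)) < 1e-9

    def test_newton_polish_from_good_guess(self, grid202, kernel202):
        inp = make_input(StimulusSpec(ps=120.0, pw=10.0), grid202)
        ss = find_steady_state(np.full(grid202.n, 0.05), kernel202, inp,
                               NetworkParams())
        u, res, ok = newton_polish(ss.u_star + 1e-4, kernel202, inp,
                                   NetworkParams())
        assert ok and res < 1e-10


class TestEnergy:
    def test_zero_for_rest(self, grid404):
        assert energy(np.zeros(grid404.n), grid404) == 0.0

    def test_constant_closed_form(self, grid404):
        c = 0.7
        assert energy(np.full(grid404.n, c), grid404) == pytest.approx(
            c * np.sqrt(2 * np.pi), rel=1e-12)

    def test_homogeneous_of_degree_one(self, grid404):
        rng = np.random.default_rng(7)
        u = rng.normal(size=grid404.n)
        assert energy(2 * u, grid404) == pytest.approx(
            2 * energy(u, grid404), rel=1e-12)
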