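"""Rate dynamics: activation, currents, integration, equivariance."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from arpnet import (
    NetworkParams,
    NetworkState,
    SynapticWeights,
    activation,
    input_currents,
    random_state,
    simulate,
    step_dynamics,
)
from conftest import permute_all


class TestActivation:
    def test_midpoint_and_saturation(self, small_params):
        p = small_params
        assert activation(p.theta, p) == pytest.approx(0.5)
        assert activation(50.0, p) == pytest.approx(1.0, abs=1e-12)
        assert activation(-50.0, p) == pytest.approx(0.0, abs=1e-12)

    def test_zero_current_gives_spontaneous_rate(self, small_params):
        assert activation(0.0, small_params) == pytest.approx(small_params.r0)

    @settings(derandomize=True, max_examples=200)
    @given(
        u1=st.floats(-2, 2, allow_nan=False),
        du=st.floats(1e-6, 2, allow_nan=False),
    )
    def test_strictly_increasing(self, u1, du):
        # moderate gain keeps the logistic away from float saturation
        p = NetworkParams(beta=10.0)
        assert activation(u1 + du, p) > activation(u1, p)

    def test_nonfinite_current_rejected(self, small_params):
        with pytest.raises(ValueError):
            activation(float("nan"), small_params)


class TestInputCurrents:
    def test_all_zero(self, small_params):
        p = small_params
        w = SynapticWeights.zeros(p)
        st0 = NetworkState(np.full(p.N, 1e-9), np.full(p.N, 1e-9))
        I_h, I_o = input_currents(st0, w, None, 0.0, p)
        np.testing.assert_allclose(I_h, 0.0, atol=1e-7)
        np.testing.assert_allclose(I_o, 0.0, atol=1e-7)

    def test_uniform_rates_closed_form_inhibition(self, small_params):
        p = small_params
        r = 0.3
        w = SynapticWeights.zeros(p)
        st0 = NetworkState(np.full(p.N, r), np.full(p.N, r))
        I_h, _ = input_currents(st0, w, None, 0.0, p)
        np.testing.assert_allclose(I_h, p.c_inh * (p.N - 1) * r)

    def test_small_instance_against_scalar_loop(self):
        p = NetworkParams(N=3, c_inh=-0.5)
        rng = np.random.default_rng(7)
        w = SynapticWeights.uniform(p, rng)
        xh = rng.uniform(0.1, 0.9, 3)
        xo = rng.uniform(0.1, 0.9, 3)
        xi = np.array([1.0, 0.0, 1.0])
        gamma = 1.7
        I_h, I_o = input_currents(NetworkState(xh, xo), w, xi, gamma, p)
        for i in range(3):
            ih = sum(w.J_ih[i, j] * gamma * xi[j] for j in range(3))
            ih += sum(w.J_oh[i, j] * xo[j] for j in range(3))
            ih += p.c_inh * sum(xh[j] for j in range(3) if j != i)
            assert I_h[i] == pytest.approx(ih)
            io = sum(w.J_ho[i, j] * xh[j] for j in range(3))
            io += p.c_inh * sum(xo[j] for j in range(3) if j != i)
            assert I_o[i] == pytest.approx(io)

    def test_dimension_mismatch_raises(self, small_params):
        p = small_params
        w = SynapticWeights.zeros(p)
        st0 = random_state(p, np.random.default_rng(0))
        with pytest.raises(ValueError):
            input_currents(st0, w, np.ones(p.N + 1), 1.0, p)


class TestStepDynamics:
    def test_fixed_point_is_stationary(self, small_params):
        p = small_params
        w = SynapticWeights.zeros(p)
        # self-consistent uniform state x = f(c_inh (N-1) x)
        from scipy.optimize import brentq

        g = lambda x: activation(p.c_inh * (p.N - 1) * x, p) - x
        xstar = brentq(g, 1e-9, 1 - 1e-9)
        st0 = NetworkState(np.full(p.N, xstar), np.full(p.N, xstar))
        st1 = step_dynamics(st0, w, None, 0.0, p)
        np.testing.assert_allclose(st1.x_hidden, st0.x_hidden, atol=1e-12)
        np.testing.assert_allclose(st1.x_output, st0.x_output, atol=1e-12)
        assert st1.t == pytest.approx(p.dt)

    def test_rates_stay_in_unit_interval(self, small_params):
        p = small_params
        rng = np.random.default_rng(3)
        w = SynapticWeights.uniform(p, rng)
        st0 = random_state(p, rng)
        for _ in range(200):
            st0 = step_dynamics(st0, w, None, 0.0, p)
        assert np.all(st0.x_hidden > 0) and np.all(st0.x_hidden < 1)
        assert np.all(st0.x_output > 0) and np.all(st0.x_output < 1)


class TestSimulate:
    def test_zero_duration_returns_initial_snapshot(self, small_params):
        p = small_params
        w = SynapticWeights.zeros(p)
        st0 = random_state(p, np.random.default_rng(1))
        trj = simulate(st0, w, None, 0.0, 0.0, p)
        assert len(trj) == 1
        np.testing.assert_array_equal(trj.hidden[0], st0.x_hidden)

    def test_bit_identical_repetition(self, small_params):
        p = small_params
        rng = np.random.default_rng(5)
        w = SynapticWeights.uniform(p, rng)
        st0 = random_state(p, rng)
        t1 = simulate(st0.copy(), w, None, 0.0, 20.0, p, record_every=10)
        t2 = simulate(st0.copy(), w, None, 0.0, 20.0, p, record_every=10)
        np.testing.assert_array_equal(t1.hidden, t2.hidden)
        np.testing.assert_array_equal(t1.output, t2.output)

    def test_converges_to_uniform_fixed_point_from_any_start(self, small_params):
        p = small_params
        w = SynapticWeights.zeros(p)
        from scipy.optimize import brentq

        g = lambda x: activation(p.c_inh * (p.N - 1) * x, p) - x
        xstar = brentq(g, 1e-9, 0.5)
        for seed in range(3):
            st0 = random_state(p, np.random.default_rng(seed))
            trj = simulate(st0, w, None, 0.0, 60.0, p, record_every=100)
            np.testing.assert_allclose(trj.hidden[-1], xstar, atol=1e-6)
            np.testing.assert_allclose(trj.output[-1], xstar, atol=1e-6)

    @pytest.mark.parametrize("perm_seed", [0, 1])
    def test_permutation_equivariance(self, perm_seed):
        # moderate gain: relabeling changes float summation order, and a
        # steep winner-take-all would amplify that roundoff exponentially
        p = NetworkParams(N=6, beta=10.0)
        rng = np.random.default_rng(42)
        w = SynapticWeights.uniform(p, rng)
        st0 = random_state(p, rng)
        xi = np.zeros(p.N)
        xi[1] = 1.0
        perm = np.random.default_rng(perm_seed).permutation(p.N)
        trj = simulate(st0, w, xi, 1.3, 1.0, p, record_every=10)
        st_p = NetworkState(st0.x_hidden[perm], st0.x_output[perm])
        trj_p = simulate(st_p, permute_all(w, perm), xi[perm], 1.3, 1.0, p,
                         record_every=10)
        np.testing.assert_allclose(trj_p.hidden, trj.hidden[:, perm], atol=1e-9)
        np.testing.assert_allclose(trj_p.output, trj.output[:, perm], atol=1e-9)

    def test_against_adaptive_reference_integrator(self):
        """Euler at small dt tracks a high-accuracy RK45 solution (N=2)."""
        from scipy.integrate import solve_ivp

        p = NetworkParams(N=2, beta=10.0, dt=2e-5)
        rng = np.random.default_rng(9)
        w = SynapticWeights.uniform(p, rng)
        st0 = random_state(p, rng)
        xi = np.array([1.0, 0.0])
        gamma = 1.0

        def rhs(t, y):
            xh, xo = y[:2], y[2:]
            I_h = gamma * (w.J_ih @ xi) + w.J_oh @ xo + p.c_inh * (xh.sum() - xh)
            I_o = w.J_ho @ xh + p.c_inh * (xo.sum() - xo)
            f = lambda u: 1.0 / (1.0 + np.exp(-p.beta * (u - p.theta)))
            return np.concatenate([(-xh + f(I_h)) / p.tau, (-xo + f(I_o)) / p.tau])

        sol = solve_ivp(
            rhs, (0, 10.0), np.concatenate([st0.x_hidden, st0.x_output]),
            rtol=1e-10, atol=1e-12, dense_output=True,
        )
        trj = simulate(st0, w, xi, gamma, 10.0, p, record_every=50000)
        for t, h, o in zip(trj.times, trj.hidden, trj.output):
            ref = sol.sol(t)
            assert np.max(np.abs(np.concatenate([h, o]) - ref)) < 1e-4

    def test_trajectory_frame_columns(self, small_params):
        p = small_params
        w = SynapticWeights.zeros(p)
        st0 = random_state(p, np.random.default_rng(1))
        df = simulate(st0, w, None, 0.0, 1.0, p, record_every=10).to_frame()
        assert list(df.columns)[:2] == ["t", "h_0"]
        assert f"o_{p.N - 1}" in df.columns
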