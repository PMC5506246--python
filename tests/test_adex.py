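"""AdEx integrator: equilibria, resets, analytic oracle, convergence."""

import numpy as np
import pytest
from dataclasses import replace
from scipy.linalg import expm

from colliculus import tuning
from colliculus.adex import (
    SC_PRESET,
    NeuronState,
    adex_step,
    integrate_neuron,
    integrate_conductance_batch,
)


class TestSingleStep:
    def test_rest_is_near_equilibrium(self):
        """At V = E_L with no input, |dV/dt| is ~ g_L eta e^{-10} / C."""
        state = NeuronState(V=SC_PRESET.E_L, q=0.0)
        new, spiked = adex_step(state, 0.0, SC_PRESET, dt=0.01)
        assert not spiked
        assert abs(new.V - state.V) / 0.01 < 1e-4

    def test_threshold_crossing_resets_and_bumps_adaptation(self):
        state = NeuronState(V=SC_PRESET.V_peak - 0.5, q=100.0)
        new, spiked = adex_step(state, 5e4, SC_PRESET, dt=0.01)
        assert spiked
        assert new.V == SC_PRESET.V_r
        assert new.q == pytest.approx(state.q + SC_PRESET.b, abs=0.1)

    def test_non_finite_input_rejected(self):
        with pytest.raises(ValueError):
            adex_step(NeuronState(np.nan, 0.0), 0.0, SC_PRESET)
        with pytest.raises(ValueError):
            adex_step(NeuronState(-70.0, 0.0), np.inf, SC_PRESET)

    def test_overflow_guard_keeps_update_finite(self):
        """A state far beyond threshold must not overflow the exponential."""
        new, spiked = adex_step(NeuronState(200.0, 0.0), 0.0, SC_PRESET, dt=0.01)
        assert spiked and np.isfinite(new.V)


class TestSubthresholdOracle:
    def test_matches_linear_ode_solution(self):
        """With the exponential term disabled, (V, q) follow a linear 2-D
        ODE whose matrix-exponential solution is the independent oracle."""
        p = replace(SC_PRESET, V_T=1e6, V_peak=2e6)  # exp term underflows
        I, T, dt = 150.0, 100.0, 0.01
        # x = V - E_L:  x' = (-g_L x - q + I)/C ; q' = (a x - q)/tau_q
        A = np.array([[-p.g_L / p.C, -1.0 / p.C], [p.a / p.tau_q, -1.0 / p.tau_q]])
        b = np.array([I / p.C, 0.0])
        x_inf = -np.linalg.solve(A, b)
        exact = expm(A * T) @ (np.array([0.0, 0.0]) - x_inf) + x_inf
        V_exact, q_exact = exact[0] + p.E_L, exact[1]

        n_steps = int(T / dt)
        _, V_tr, q_tr = integrate_neuron(
            p, dt=dt, horizon=T, current=np.full(n_steps, I), record=True
        )
        assert V_tr[-1] == pytest.approx(V_exact, rel=1e-3)
        assert q_tr[-1] == pytest.approx(q_exact, rel=1e-3)


class TestBurstDynamics:
    def test_quiescent_without_input(self):
        assert integrate_neuron(SC_PRESET, horizon=50.0).size == 0

    def test_contour_pair_reproduces_twenty_spikes(self, grid_result, ref_train):
        """A grid point on the 20-spike contour re-simulates to 20 spikes."""
        tau, w = (v[0] for v in grid_result.contour_points())
        train = integrate_conductance_batch([tau], [w], ref_train)[0]
        assert train.size == 20

    def test_adaptation_accumulates_across_burst(self, quadratic, ref_train):
        """Bursts terminate through q: the adaptation current sampled at
        successive spikes rises monotonically through the burst."""
        tau = 45.0
        w = float(np.polyval(quadratic, tau))
        p = SC_PRESET.with_tau_q(tau)
        times, _, q_tr = integrate_neuron(
            p, horizon=300.0, presyn_times=ref_train, w=w, record=True
        )
        assert times.size >= 15
        burst = times[:15]  # core burst, before any straggler spikes
        q_at_spikes = q_tr[(burst / 0.01).astype(int) - 1]
        # strict growth while ISIs are short (early burst); net accumulation
        # over the whole burst (a lengthening ISI can dip q transiently)
        assert np.all(np.diff(q_at_spikes[:8]) > 0)
        assert q_at_spikes[-1] > 5 * q_at_spikes[0]

    def test_spike_times_strictly_increasing(self, ref_train, quadratic):
        w = float(np.polyval(quadratic, 30.0))
        t = integrate_conductance_batch([30.0], [w], ref_train)[0]
        assert np.all(np.diff(t) > 0)


class TestConvergence:
    """Forward-Euler refinement: the trajectory converges as dt shrinks.

    Early spike times converge at first order; late-burst spikes of this
    knife-edge bursting system accumulate timing drift across resets, so
    convergence is asserted on counts and the early burst.
    """

    def test_input_layer_count_stable_under_refinement(self):
        t1 = tuning.reference_fef_train(dt=0.01)
        t2 = tuning.reference_fef_train(dt=0.005)
        assert t1.size == t2.size

    def test_first_spike_time_converges(self):
        t1 = tuning.reference_fef_train(dt=0.01)
        t2 = tuning.reference_fef_train(dt=0.005)
        assert abs(t1[0] - t2[0]) < 0.05

    def test_early_spike_error_shrinks_with_dt(self):
        trains = {dt: tuning.reference_fef_train(dt=dt) for dt in (0.02, 0.01, 0.005)}
        coarse = np.abs(trains[0.02][:5] - trains[0.01][:5]).max()
        fine = np.abs(trains[0.01][:5] - trains[0.005][:5]).max()
        assert fine < coarse

    def test_tuned_sc_neuron_count_stable_under_refinement(self, quadratic):
        tau = 80.0
        w = float(np.polyval(quadratic, tau))
        out = {}
        for dt in (0.01, 0.005):
            ref = tuning.reference_fef_train(dt=dt)
            out[dt] = integrate_conductance_batch([tau], [w], ref, dt=dt)[0]
        assert out[0.01].size == out[0.005].size
        k = min(10, out[0.01].size)
        assert np.abs(out[0.01][:k] - out[0.005][:k]).max() < 0.5
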