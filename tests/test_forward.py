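"""Population dynamics and hemodynamic forward model."""

import numpy as np
import pytest
from scipy.optimize import fsolve

from neuroinflux.forward import (
    HemoParams,
    NeuralModelParams,
    NeuralTrace,
    bold_forward,
    neural_drift,
    sigmoid,
    simulate_neural,
)


class TestSigmoid:
    def test_midpoint_is_half(self):
        assert sigmoid(4.0, gain=1.3, threshold=4.0) == pytest.approx(0.5)

    def test_saturation(self):
        assert sigmoid(1e3, 1.0, 0.0) == pytest.approx(1.0)
        assert sigmoid(-1e3, 1.0, 0.0) == pytest.approx(0.0, abs=1e-12)

    def test_closed_form_value(self):
        assert sigmoid(2.0, gain=2.0, threshold=1.0) == pytest.approx(
            1.0 / (1.0 + np.exp(-2.0)), abs=1e-12
        )

    def test_strictly_increasing(self):
        x = np.linspace(-5, 5, 101)
        assert np.all(np.diff(sigmoid(x, 1.3, 0.5)) > 0)

    def test_nonpositive_gain_rejected(self):
        with pytest.raises(ValueError):
            sigmoid(0.0, gain=0.0, threshold=0.0)


def _uncoupled_fixed_point(params, drive):
    """Root of the isolated 2-D unit found by an independent solver."""
    def resid(x):
        e, i = x
        dE, dI = neural_drift([e], [i], params, np.zeros((1, 1)), [drive])
        return [dE[0], dI[0]]

    sol = fsolve(resid, [0.05, 0.05], full_output=True)
    assert sol[2] == 1, "root finding failed"
    return sol[0]


class TestNeuralDrift:
    params = NeuralModelParams(noise_sd=0.0)

    def test_uncoupled_regions_independent(self):
        params = NeuralModelParams(G_coupling=0.0, noise_sd=0.0)
        C = np.ones((3, 3)) - np.eye(3)
        a = np.array([0.3, 0.4, 0.5])
        E = np.array([0.1, 0.2, 0.3])
        I = np.array([0.05, 0.1, 0.15])
        dE1, _ = neural_drift(E, I, params, C, a)
        E2 = E.copy()
        E2[1] = 0.9  # perturbing another region must not change region 0
        dE2, _ = neural_drift(E2, I, params, C, a)
        assert dE1[0] == dE2[0]

    def test_drift_vanishes_at_root_found_independently(self):
        e, i = _uncoupled_fixed_point(self.params, drive=0.4)
        dE, dI = neural_drift([e], [i], self.params, np.zeros((1, 1)), [0.4])
        assert abs(dE[0]) < 1e-10 and abs(dI[0]) < 1e-10

    def test_permutation_symmetry_two_regions(self):
        C = np.array([[0.0, 1.0], [1.0, 0.0]])
        dE, dI = neural_drift([0.2, 0.2], [0.1, 0.1], self.params, C,
                              [0.5, 0.5])
        assert dE[0] == dE[1] and dI[0] == dI[1]

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            neural_drift([0.1], [0.1, 0.2], self.params, np.zeros((2, 2)),
                         [0.3, 0.3])


def _euler_reference(params, C, a, duration, dt):
    """Plain-numpy deterministic Euler integrator (independent of the
    compiled kernel's code path)."""
    C = np.asarray(C, float)
    s = C.sum(axis=1).max()
    Cn = C / s if s > 0 else C
    n_steps = int(round(duration / dt))
    E = np.full(len(a), 0.1)
    I = np.full(len(a), 0.1)
    for _ in range(n_steps):
        dE, dI = neural_drift(E, I, params, Cn, a)
        E = np.clip(E + dt * dE, 0, 1)
        I = np.clip(I + dt * dI, 0, 1)
    return E, I


class TestSimulateNeural:
    def test_constant_at_fixed_point_without_noise(self):
        params = NeuralModelParams(noise_sd=0.0, G_coupling=0.0)
        e, i = _uncoupled_fixed_point(params, drive=0.4)
        trace = simulate_neural(params, np.zeros((1, 1)), [0.4], 10.0, 0.002,
                                initial_state=(e, i))
        assert np.all(np.abs(trace.E - e) < 1e-8)
        assert np.all(np.abs(trace.I - i) < 1e-8)

    def test_same_seed_reproduces_trace_bitwise(self):
        params = NeuralModelParams(noise_sd=0.05)
        C = np.array([[0, 1.0], [1.0, 0]])
        t1 = simulate_neural(params, C, [0.4, 0.5], 5.0, 0.002, seed=42)
        t2 = simulate_neural(params, C, [0.4, 0.5], 5.0, 0.002, seed=42)
        np.testing.assert_array_equal(t1.E, t2.E)
        np.testing.assert_array_equal(t1.I, t2.I)

    def test_different_seed_differs(self):
        params = NeuralModelParams(noise_sd=0.05)
        t1 = simulate_neural(params, np.zeros((1, 1)), [0.4], 5.0, 0.002, seed=1)
        t2 = simulate_neural(params, np.zeros((1, 1)), [0.4], 5.0, 0.002, seed=2)
        assert not np.array_equal(t1.E, t2.E)

    def test_states_stay_in_unit_interval(self):
        params = NeuralModelParams(noise_sd=0.3, G_coupling=1.0)
        C = np.ones((3, 3)) - np.eye(3)
        trace = simulate_neural(params, C, [2.0, 0.0, 5.0], 5.0, 0.002, seed=0)
        assert trace.E.min() >= 0 and trace.E.max() <= 1
        assert trace.I.min() >= 0 and trace.I.max() <= 1

    def test_matches_independent_integrator_and_first_order_in_dt(self):
        params = NeuralModelParams(noise_sd=0.0, G_coupling=0.4)
        C = np.array([[0, 1.0, 0.5], [1.0, 0, 0.2], [0.5, 0.2, 0]])
        a = np.array([0.3, 0.5, 0.7])
        duration, dt = 2.0, 0.002
        trace = simulate_neural(params, C, a, duration, dt)
        # independent plain-numpy integrator at the same step
        E_ref, _ = _euler_reference(params, C, a, duration, dt)
        np.testing.assert_allclose(trace.E[-1], E_ref, atol=1e-8)
        # halving dt: noise-free end states converge at first order
        fine = simulate_neural(params, C, a, duration, dt / 10)
        err_coarse = np.abs(trace.E[-1] - fine.E[-1]).max()
        finer = simulate_neural(params, C, a, duration, dt / 2)
        err_half = np.abs(finer.E[-1] - fine.E[-1]).max()
        assert err_coarse < 0.05  # O(dt) scale for dt = 2 ms
        assert err_half < err_coarse


class TestBoldForward:
    hemo = HemoParams()

    def _trace_from_E(self, E, dt=0.002):
        E = np.asarray(E, float)
        times = np.arange(E.shape[0]) * dt
        return NeuralTrace(times=times, E=E, I=np.zeros_like(E), dt=dt)

    def test_zero_drive_from_rest_gives_zero_bold(self):
        trace = self._trace_from_E(np.zeros((20001, 2)))
        bold = bold_forward(trace, self.hemo, TR=2.0, n_volumes=10, burn_in=0.0)
        np.testing.assert_allclose(bold.signals, 0.0, atol=1e-12)

    def test_pulse_response_single_peak_returning_to_baseline(self):
        dt = 0.002
        n_steps = int(60.0 / dt)
        E = np.zeros((n_steps + 1, 1))
        E[int(5.0 / dt):int(5.5 / dt)] = 0.5  # 0.5 s pulse at t = 5 s
        trace = self._trace_from_E(E, dt)
        bold = bold_forward(trace, self.hemo, TR=0.5, n_volumes=119,
                            burn_in=0.0)
        sig = bold.signals[:, 0]
        peak = int(np.argmax(sig))
        assert sig[peak] > 0
        assert 5.0 < peak * 0.5 < 15.0  # hemodynamic delay of a few seconds
        # single prominent positive peak: rises before, decays after
        assert np.all(np.diff(sig[: peak + 1]) >= -1e-9)
        assert abs(sig[-1]) < 1e-3  # returns toward baseline

    def test_shape_contract(self):
        E = np.zeros((int(430 / 0.002) + 1, 3))
        trace = self._trace_from_E(E)
        bold = bold_forward(trace, self.hemo, TR=2.0, n_volumes=200,
                            burn_in=30.0)
        assert bold.signals.shape == (200, 3)

    def test_trace_dump_round_trips(self, tmp_path):
        import pandas as pd

        from neuroinflux.forward import trace_to_csv

        params = NeuralModelParams(noise_sd=0.02)
        trace = simulate_neural(params, np.zeros((2, 2)), [0.3, 0.5], 0.5,
                                0.002, seed=1)
        path = trace_to_csv(trace, tmp_path / "trace.csv", ["A", "B"])
        back = pd.read_csv(path, float_precision="round_trip")
        np.testing.assert_array_equal(back["E_A"].to_numpy(), trace.E[:, 0])
        np.testing.assert_array_equal(back["I_B"].to_numpy(), trace.I[:, 1])

    def test_too_short_trace_rejected(self):
        trace = self._trace_from_E(np.zeros((100, 1)))
        with pytest.raises(ValueError, match="trace covers"):
            bold_forward(trace, self.hemo, TR=2.0, n_volumes=10, burn_in=0.0)
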