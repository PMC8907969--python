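"""AdEx point-neuron dynamics: closed-form checks and ISI classification."""

import numpy as np
import pytest

from analognet.neuron import (
    AdExParameters,
    ClassifierThresholds,
    NeuronState,
    SpikeTrain,
    StimulusProtocol,
    classify_firing_pattern,
    convert_biological_params,
    run_neuron,
    simulate_adex_batch,
    step_neuron,
)
from analognet.patterns import PATTERN_SETS, default_protocol


def lif_params(**kw):
    base = dict(enable_exp=False, enable_adapt=False)
    base.update(kw)
    return AdExParameters(**base)


class TestParameterConversion:
    def test_time_constants_divide_by_acceleration(self):
        bio = AdExParameters(
            C_m=2e-10, g_l=1e-8, tau_w=0.1, t_r=2e-3, domain="biological"
        )
        hw = convert_biological_params(bio, 1000.0)
        assert hw.tau_m == pytest.approx(bio.tau_m / 1000.0)
        assert hw.tau_w == pytest.approx(bio.tau_w / 1000.0)
        assert hw.t_r == pytest.approx(bio.t_r / 1000.0)
        assert hw.E_l == bio.E_l and hw.V_T == bio.V_T  # voltages unchanged
        assert hw.domain == "hardware"

    def test_ten_ms_maps_to_ten_us(self):
        bio = AdExParameters(C_m=2e-10, g_l=2e-8, domain="biological")
        assert bio.tau_m == pytest.approx(10e-3)
        assert convert_biological_params(bio).tau_m == pytest.approx(10e-6)

    def test_identity_and_round_trip(self):
        p = AdExParameters(a=1e-9, b=2e-9)
        same = convert_biological_params(p, 1.0)
        assert same.g_l == p.g_l and same.tau_w == p.tau_w
        back = convert_biological_params(convert_biological_params(p, 7.0), 1 / 7.0)
        for f in ("g_l", "a", "b", "tau_w", "t_r", "I_exp_max"):
            assert getattr(back, f) == pytest.approx(getattr(p, f), rel=1e-12)

    def test_nonpositive_acceleration_rejected(self):
        with pytest.raises(ValueError):
            convert_biological_params(AdExParameters(), 0.0)


class TestStepNeuron:
    def test_lif_fixed_point(self):
        p = lif_params()
        s = NeuronState(V=p.E_l, w=0.0)
        s2 = step_neuron(s, p, I_in=0.0, dt=1e-7)
        assert s2.V == pytest.approx(p.E_l)
        assert s2.w == 0.0

    def test_lif_charging_curve(self):
        p = lif_params()
        I, T = 1e-8, 30e-6
        dt = p.tau_m / 100
        n = int(round(T / dt))
        s = NeuronState(V=p.E_l)
        for k in range(n):
            s = step_neuron(s, p, I, dt)
        expected = p.E_l + (I / p.g_l) * (1 - np.exp(-T / p.tau_m))
        assert s.V == pytest.approx(expected, rel=1e-4)

    def test_adaptation_decay_closed_form(self):
        p = AdExParameters(enable_exp=False, a=0.0, tau_w=20e-6)
        w0, T = 5e-9, 40e-6
        dt = p.tau_w / 200
        s = NeuronState(V=p.E_l, w=w0)
        for _ in range(int(round(T / dt))):
            s = step_neuron(s, p, I_in=s.w, dt=dt)  # hold V at E_l
            s.V = p.E_l
        assert s.w == pytest.approx(w0 * np.exp(-T / p.tau_w), rel=1e-4)

    def test_nonfinite_state_rejected_with_diagnostic(self):
        with pytest.raises(FloatingPointError, match="V"):
            step_neuron(NeuronState(V=np.nan), lif_params(), 0.0, 1e-7)


class TestRunNeuron:
    def test_no_stimulus_silent_at_rest(self):
        p, proto = PATTERN_SETS["tonic"]
        proto0 = StimulusProtocol(I_0=0.0, t_on=proto.t_on,
                                  t_off=proto.t_off, T=proto.T)
        _, V, _, spikes = run_neuron(p, proto0)
        assert len(spikes) == 0
        assert np.allclose(V, p.E_l, atol=1e-12)

    def test_refractoriness_bounds_isis(self):
        p, proto = PATTERN_SETS["tonic"]
        dt = 1e-7
        _, _, _, spikes = run_neuron(p, proto, dt=dt)
        assert len(spikes) > 3
        assert np.all(spikes.isis() >= p.t_r - dt)

    def test_spike_triggered_adaptation_increment(self):
        p, proto = PATTERN_SETS["regular_bursting"]
        _, _, w, spikes = run_neuron(p, proto)
        k = int(spikes.times[0] / 1e-7)
        assert w[k + 1] - w[k] == pytest.approx(p.b, rel=0.05)

    def test_integrator_mode_charge_conservation(self):
        p = AdExParameters(enable_exp=False, enable_adapt=False,
                           enable_leak=False, enable_threshold=False)
        rng = np.random.default_rng(3)
        dt, n = 1e-7, 500
        I = rng.normal(0, 1e-9, (n, 1))
        _, V, _, _ = simulate_adex_batch([p], I, n * dt, dt)
        expected = p.E_l + I.sum() * dt / p.C_m
        assert V[-1, 0] == pytest.approx(expected, rel=1e-6)

    def test_burst_period_limit_cycle_stability(self):
        p, proto = PATTERN_SETS["regular_bursting"]
        _, _, _, spikes = run_neuron(p, proto)
        ts = spikes.times
        isis = np.diff(ts)
        # burst onsets = spikes following a long (inter-burst) gap
        split = np.sqrt(isis.min() * isis.max())
        onsets = ts[1:][isis > split]
        periods = np.diff(onsets)
        assert len(periods) >= 3
        periods = periods[2:] if len(periods) > 3 else periods
        assert periods.std() / periods.mean() < 0.02

    def test_spike_times_first_order_in_dt(self):
        p, proto = PATTERN_SETS["tonic"]
        t_coarse = run_neuron(p, proto, dt=2e-7)[3].times[0]
        t_fine = run_neuron(p, proto, dt=1e-7)[3].times[0]
        t_ref = run_neuron(p, proto, dt=2.5e-8)[3].times[0]
        assert abs(t_coarse - t_ref) < 4 * 2e-7
        assert abs(t_fine - t_ref) <= abs(t_coarse - t_ref) + 1e-9


class TestClassifier:
    PROTO = default_protocol(1e-8)

    def _train(self, times):
        return SpikeTrain(times)

    def test_empty_train_is_silent(self):
        assert classify_firing_pattern(self._train([]), self.PROTO) == "silent"

    def test_single_early_spike_is_transient(self):
        t = self._train([self.PROTO.t_on + 5e-6])
        assert classify_firing_pattern(t, self.PROTO) == "transient"

    def test_synthetic_bimodal_isis_are_regular_bursting(self):
        # ISI sequence (2, 2, 20, 2, 2, 20, ...) us repeating until t_off;
        # oracle: intra/inter split 2/20 = 0.1 < 0.25
        t0 = self.PROTO.t_on + 2e-6
        times, t = [], t0
        while t < self.PROTO.t_off - 5e-6:
            for isi in (2e-6, 2e-6, 20e-6):
                times.append(t)
                t += isi
        lab = classify_firing_pattern(self._train(times), self.PROTO)
        assert lab == "regular_bursting"

    def test_regular_isis_are_tonic(self):
        times = np.arange(self.PROTO.t_on + 5e-6, self.PROTO.t_off, 8e-6)
        assert classify_firing_pattern(self._train(times), self.PROTO) == "tonic"

    def test_spikes_outside_window_rejected(self):
        with pytest.raises(ValueError):
            classify_firing_pattern(self._train([self.PROTO.T + 1e-6]), self.PROTO)

    def test_thresholds_configurable(self):
        th = ClassifierThresholds(transient_frac=0.9)
        times = np.arange(self.PROTO.t_on + 5e-6,
                          self.PROTO.t_on + 0.5 * 350e-6, 8e-6)
        assert classify_firing_pattern(self._train(times), self.PROTO, th) \
            == "transient"
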