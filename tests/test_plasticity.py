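"""Correlation sensors, CADC readout, rule scheduling and homeostasis."""

import numpy as np
import pytest

from analognet.plasticity import (
    CADCModel,
    CorrelationSensorArray,
    PlasticityRule,
    StaticCrossbarContext,
    accumulate_pair_correlations,
    cadc_read,
    estimate_autocorrelation_time,
    homeostatic_update,
    run_plasticity_schedule,
    update_correlation,
)
from analognet.reservoir import ReservoirExperiment, ReservoirNetwork


class TestCorrelationSensors:
    def test_single_pair_closed_form(self):
        tau = 10e-6
        cc, ca = accumulate_pair_correlations([0.0], [tau], eta=1.0,
                                              tau_plus=tau)
        assert cc == pytest.approx(np.exp(-1.0))
        assert ca == 0.0

    def test_no_post_spikes_leaves_zero(self):
        cc, ca = accumulate_pair_correlations([1e-6, 2e-6], [])
        assert cc == 0.0 and ca == 0.0

    def test_increment_monotone_in_pair_delay(self):
        c1, _ = accumulate_pair_correlations([0.0], [1e-6])
        c10, _ = accumulate_pair_correlations([0.0], [10e-6])
        assert c1 > c10

    def test_nearest_preceding_pairing_exact_for_arbitrary_lists(self):
        rng = np.random.default_rng(9)
        pre = np.sort(rng.uniform(0, 100e-6, 20))
        post = np.sort(rng.uniform(0, 100e-6, 20))
        eta, tp, tm = 0.8, 7e-6, 12e-6
        cc, ca = accumulate_pair_correlations(pre, post, eta, tp, tm)
        # independent direct re-evaluation
        cc_ref = sum(
            eta * np.exp(-(t - pre[pre <= t].max()) / tp)
            for t in post if np.any(pre <= t)
        )
        ca_ref = sum(
            eta * np.exp(-(t - post[post <= t].max()) / tm)
            for t in pre if np.any(post <= t)
        )
        assert cc == pytest.approx(cc_ref, abs=1e-9)
        assert ca == pytest.approx(ca_ref, abs=1e-9)

    def test_array_accumulation_and_reset(self):
        arr = CorrelationSensorArray((2, 2), tau_plus=5e-6)
        update_correlation(arr, (0, 1), [0.0], [5e-6])
        assert arr.c_causal[0, 1] == pytest.approx(np.exp(-1.0))
        arr.reset((0, 1))
        assert arr.c_causal[0, 1] == 0.0


class TestCADC:
    def test_saturation_at_full_scale(self):
        cadc = CADCModel(v_min=0.0, v_max=1.0)
        assert cadc_read(np.array([2.0]), cadc)[0] == 255
        assert cadc_read(np.array([-1.0]), cadc)[0] == 0

    def test_reset_on_read(self):
        sensors = CorrelationSensorArray((4,))
        sensors.c_causal[:] = 0.5
        cadc = CADCModel()
        first = cadc_read(sensors.c_causal.copy(), cadc, sensors=sensors,
                          index=slice(None), reset=True)
        second = cadc_read(sensors.c_causal.copy(), cadc, sensors=sensors,
                           index=slice(None))
        assert np.all(first > 0)
        assert np.all(second == 0)

    def test_quantization_bound_random_sample(self):
        rng = np.random.default_rng(1)
        cadc = CADCModel(v_min=0.0, v_max=1.0)
        v = rng.random(1000)
        codes = cadc.quantize(v)
        assert np.all(np.abs(cadc.dequantize(codes) - v) <= 0.5 * cadc.step + 1e-15)


class TestScheduler:
    def test_identity_rule_keeps_weights(self):
        ctx = StaticCrossbarContext(np.full((4, 8), 33))
        rule = PlasticityRule(period=1e-5, callback=lambda v: v.weights)
        log = run_plasticity_schedule(ctx, rule, duration=1e-3)
        assert log == []
        assert np.all(ctx.weights == 33)

    def test_decrement_rule_arithmetic(self):
        ctx = StaticCrossbarContext(np.full((1, 4), 63))
        rule = PlasticityRule(period=1e-5, callback=lambda v: v.weights - 1)
        run_plasticity_schedule(ctx, rule, duration=10e-5)
        assert np.all(ctx.weights == 53)

    def test_writes_clipped_to_weight_range_and_logged(self):
        ctx = StaticCrossbarContext(np.full((1, 3), 2))
        rule = PlasticityRule(period=1e-5, callback=lambda v: v.weights - 5)
        log = run_plasticity_schedule(ctx, rule, duration=2e-5)
        assert np.all(ctx.weights == 0)
        assert all(0 <= new <= 63 for *_, new in log)

    def test_audit_log_replays_final_state(self):
        rng = np.random.default_rng(12)
        w0 = rng.integers(0, 64, (3, 5))
        ctx = StaticCrossbarContext(w0)

        def noisy(view):
            return view.weights + rng.integers(-2, 3, view.weights.shape)

        log = run_plasticity_schedule(
            ctx, PlasticityRule(period=1e-5, callback=noisy), duration=8e-5
        )
        replay = w0.copy()
        for _, row, col, old, new in log:
            assert replay[row, col] == old
            replay[row, col] = new
        np.testing.assert_array_equal(replay, ctx.weights)

    def test_stdp_rule_strictly_nondecreasing_under_causal_pairs(self):
        sensors = CorrelationSensorArray((1, 4))
        ctx = StaticCrossbarContext(np.full((1, 4), 10))
        period = 1e-5

        def stdp(view):
            update_correlation(sensors, (0, slice(None)), [view.time - 6e-6],
                               [view.time - 1e-6])
            dw = np.round(2.0 * (sensors.c_causal[0] - sensors.c_acausal[0]))
            sensors.reset()
            return view.weights + dw.astype(int)

        run_plasticity_schedule(ctx, PlasticityRule(period, stdp), 10 * period)
        assert np.all(ctx.weights >= 10)
        assert np.all(ctx.weights > 10)


class TestHomeostasis:
    def test_on_target_rate_gives_zero_step(self):
        assert np.all(homeostatic_update(np.array([100.0]), 100.0) == 0)

    def test_silent_neuron_gets_maximal_positive_step(self):
        dw = homeostatic_update(np.array([0.0]), 100.0, lambda_h=1)
        assert dw[0] == 1
        dw = homeostatic_update(np.array([0.0]), 100.0, lambda_h=5, delta_max=2)
        assert dw[0] == 2

    def test_closed_loop_rate_converges_to_target(self):
        # single LIF neuron, Poisson input, no recurrence: after 200
        # homeostatic updates the stationary rate sits within 10% of target
        exp = ReservoirExperiment(N=1, n_inputs=8, K_ext=4,
                                  nu_target=30e3, seed=5)
        net = ReservoirNetwork(exp, p_rec=0.0)
        steps_per_update = int(round(net.homeo_period / net.dt))
        net.run(200 * steps_per_update, np.full(8, 50e3), homeostasis=True)
        pop, _ = net.run(100 * steps_per_update, np.full(8, 50e3),
                         homeostasis=True)
        rate = pop.sum() / (pop.size * net.dt)
        assert rate == pytest.approx(exp.nu_target, rel=0.10)


class TestAutocorrelationTime:
    def test_white_noise_is_memoryless(self):
        rng = np.random.default_rng(3)
        tau, diag = estimate_autocorrelation_time(rng.normal(size=20000), 1e-6)
        assert tau < 2e-6

    def test_ar1_closed_form(self):
        rng = np.random.default_rng(4)
        phi, n = 0.9, 100000
        x = np.empty(n)
        x[0] = 0.0
        eps = rng.normal(size=n)
        for k in range(1, n):
            x[k] = phi * x[k - 1] + eps[k]
        bin_w = 1e-6
        tau, diag = estimate_autocorrelation_time(x, bin_w)
        assert diag["reliable"]
        assert tau == pytest.approx(-bin_w / np.log(phi), rel=0.10)

    def test_shuffling_destroys_correlation(self):
        rng = np.random.default_rng(6)
        phi, n = 0.95, 30000
        x = np.empty(n)
        x[0] = 0.0
        for k in range(1, n):
            x[k] = phi * x[k - 1] + rng.normal()
        tau, _ = estimate_autocorrelation_time(x, 1.0)
        xs = rng.permutation(x)
        tau_s, _ = estimate_autocorrelation_time(xs, 1.0)
        assert tau_s <= tau

    def test_constant_series_flagged_unreliable(self):
        tau, diag = estimate_autocorrelation_time(np.ones(1000), 1.0)
        assert not diag["reliable"]
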