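"""Crossbar event delivery, exponential currents and analog MAC mode."""

import numpy as np
import pytest

from analognet import constants as C
from analognet.crossbar import (
    EventPacket,
    MACConfig,
    Synapse,
    SynapseArray,
    SynapticState,
    decay_currents,
    deliver_event,
    mac_forward,
    mac_tiled,
    synaptic_current_at,
)


def small_state(n=3, gamma=1.0, tau=2e-6):
    return SynapticState(n_neurons=n, gamma=gamma,
                         tau_syn_exc=tau, tau_syn_inh=tau)


class TestDeliverEvent:
    def test_address_matching_row_example(self):
        arr = SynapseArray()
        arr.set_row(0, 0, weights=[10, 20, 30], addresses=[5, 7, 5])
        st = small_state()
        deliver_event(arr, st, EventPacket(0.0, row=0, label=5))
        assert st.I_exc[0] == pytest.approx(10.0)
        assert st.I_exc[1] == 0.0
        assert st.I_exc[2] == pytest.approx(30.0)

    def test_zero_weight_increments_exactly_zero(self):
        arr = SynapseArray()
        arr.set_row(0, 0, weights=[0], addresses=[1])
        st = small_state(1)
        deliver_event(arr, st, EventPacket(0.0, row=0, label=1))
        assert st.I_exc[0] == 0.0

    def test_inhibitory_row_targets_inhibitory_current(self):
        arr = SynapseArray()
        arr.set_row(0, 0, weights=[7], addresses=[3], sign=-1)
        st = small_state(1)
        deliver_event(arr, st, EventPacket(0.0, row=0, label=3))
        assert st.I_inh[0] == pytest.approx(7.0)
        assert st.I_exc[0] == 0.0

    def test_disabled_row_drops_and_counts(self):
        arr = SynapseArray()
        arr.set_row(0, 0, weights=[9], addresses=[0], enabled=False)
        st = small_state(1)
        deliver_event(arr, st, EventPacket(0.0, row=0, label=0))
        assert st.I_exc[0] == 0.0
        assert arr.dropped_events == 1

    def test_graded_payload_scales_linearly(self):
        arr = SynapseArray()
        arr.set_row(0, 0, weights=[31], addresses=[0])
        full, half = small_state(1), small_state(1)
        deliver_event(arr, full, EventPacket(0.0, 0, 0, payload=31))
        deliver_event(arr, half, EventPacket(0.0, 0, 0, payload=16))
        assert half.I_exc[0] == pytest.approx(full.I_exc[0] * 16 / 31)

    def test_address_matching_exact_over_all_labels(self):
        rng = np.random.default_rng(11)
        arr = SynapseArray()
        w = rng.integers(1, 64, 128)
        a = rng.integers(0, 64, 128)
        arr.set_row(0, 0, weights=w, addresses=a)
        for label in range(64):
            st = SynapticState(n_neurons=128, gamma=1.0)
            deliver_event(arr, st, EventPacket(0.0, 0, label))
            expected = np.where(a == label, w, 0).astype(float)
            np.testing.assert_array_equal(st.I_exc, expected)

    def test_out_of_range_fields_rejected(self):
        with pytest.raises(ValueError):
            Synapse(weight=64, address=0)
        with pytest.raises(ValueError):
            EventPacket(0.0, 0, label=64)
        with pytest.raises(ValueError):
            EventPacket(0.0, 0, label=0, payload=32)


class TestDecay:
    def test_one_time_constant_gives_e_minus_one(self):
        st = small_state(1)
        st.I_exc[0] = 1.0
        decay_currents(st, st.tau_syn_exc)
        assert st.I_exc[0] == pytest.approx(np.exp(-1.0))

    def test_zero_dt_unchanged(self):
        st = small_state(1)
        st.I_exc[0] = 0.7
        decay_currents(st, 0.0)
        assert st.I_exc[0] == 0.7

    def test_event_driven_current_matches_closed_form(self):
        # arbitrary event list; decay is analytic so agreement is exact
        rng = np.random.default_rng(5)
        tau, gamma = 3e-6, 1.0
        events = sorted(
            (float(t), float(w))
            for t, w in zip(rng.uniform(0, 50e-6, 25), rng.integers(1, 64, 25))
        )
        arr = SynapseArray()
        st = small_state(1, tau=tau)
        t_now = 0.0
        for t_ev, w in events:
            decay_currents(st, t_ev - t_now)
            arr.set_row(0, 0, weights=[int(w)], addresses=[0])
            deliver_event(arr, st, EventPacket(t_ev, 0, 0))
            t_now = t_ev
        t_end = 60e-6
        decay_currents(st, t_end - t_now)
        expected = synaptic_current_at(events, t_end, tau, gamma)
        assert st.I_exc[0] == pytest.approx(expected, abs=1e-9)

    def test_two_identical_events_superpose(self):
        tau = 2e-6
        arr = SynapseArray()
        arr.set_row(0, 0, weights=[40], addresses=[0])
        st = small_state(1, tau=tau)
        deliver_event(arr, st, EventPacket(0.0, 0, 0))
        decay_currents(st, tau)
        deliver_event(arr, st, EventPacket(tau, 0, 0))
        assert st.I_exc[0] == pytest.approx(40.0 * (1 + np.exp(-1)))

    def test_decay_is_linear(self):
        a, b = small_state(4), small_state(4)
        rng = np.random.default_rng(0)
        a.I_exc = rng.random(4)
        b.I_exc = rng.random(4)
        s = small_state(4)
        s.I_exc = a.I_exc + b.I_exc
        for st in (a, b, s):
            decay_currents(st, 1e-6)
        np.testing.assert_allclose(s.I_exc, a.I_exc + b.I_exc, rtol=1e-14)


class TestMAC:
    def scale(self, cfg=None):
        cfg = cfg or MACConfig()
        return cfg.gamma_charge / cfg.C_m

    def test_zero_input_gives_zero_output(self):
        W = np.diag([10, -20, 30])
        out = mac_forward(W, np.zeros(3), quantize=False)
        np.testing.assert_array_equal(out, 0.0)

    def test_diagonal_matrix_elementwise_products(self):
        rng = np.random.default_rng(2)
        w = rng.integers(-63, 64, 32)
        x = rng.integers(0, 32, 32) / 31.0   # on the payload grid
        out = mac_forward(np.diag(w), x, quantize=False) / self.scale()
        exact = w * x
        r = np.corrcoef(out, exact)[0, 1]
        assert r >= 0.999
        np.testing.assert_allclose(out, exact, atol=1e-9)

    def test_signed_row_pair_negation_identity(self):
        x = np.linspace(0, 1, 16)
        plus = mac_forward(np.full((4, 16), 21), x, quantize=False)
        minus = mac_forward(np.full((4, 16), -21), x, quantize=False)
        np.testing.assert_allclose(minus, -plus, atol=1e-18)

    def test_linearity_in_both_arguments(self):
        rng = np.random.default_rng(8)
        W = rng.integers(-31, 32, (8, 16))
        x = rng.integers(0, 32, 16) / 31.0
        base = mac_forward(W, x, quantize=False)
        np.testing.assert_allclose(
            mac_forward(2 * W, x, quantize=False), 2 * base, rtol=1e-6, atol=1e-18
        )

    def test_quantization_error_within_half_lsb(self):
        rng = np.random.default_rng(4)
        cfg = MACConfig()
        W = rng.integers(-63, 64, (16, 16))
        x = rng.integers(0, 32, 16) / 31.0
        q = mac_forward(W, x, quantize=True, config=cfg)
        u = mac_forward(W, x, quantize=False, config=cfg)
        assert np.all(np.abs(q - np.clip(u, -cfg.dynamic_range, cfg.dynamic_range))
                      <= 0.5 * cfg.lsb + 1e-18)

    def test_input_and_weight_validation(self):
        with pytest.raises(ValueError):
            mac_forward(np.eye(2, dtype=int), np.array([0.5, 1.2]))
        with pytest.raises(ValueError):
            mac_forward(np.array([[70, 0], [0, 1]]), np.array([0.5, 0.5]))

    def test_tiled_equals_single_block_when_it_fits(self):
        rng = np.random.default_rng(6)
        W = rng.integers(-63, 64, (20, 40))
        x = rng.integers(0, 32, 40) / 31.0
        np.testing.assert_allclose(
            mac_tiled(W, x, quantize=False),
            mac_forward(W, x, quantize=False),
            rtol=1e-12,
        )

    def test_tiled_large_matrix_matches_exact_product(self):
        rng = np.random.default_rng(7)
        W = rng.integers(-63, 64, (200, 600))
        x = rng.integers(0, 32, 600) / 31.0
        out = mac_tiled(W, x, quantize=False) / self.scale()
        exact = W @ x
        np.testing.assert_allclose(out, exact, rtol=1e-6, atol=1e-8)
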