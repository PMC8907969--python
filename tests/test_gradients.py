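"""Event-based adjoint gradients: closed forms, FD oracle, composition."""

import numpy as np
import pytest

from analognet.gradients import (
    GrazingEventError,
    LIFSystem,
    LossSpec,
    backward_adjoint,
    evaluate_loss,
    event_time_derivative,
    finite_difference_gradient,
    forward_hybrid,
    run_gradcheck,
)

DT = 0.05e-6


def terminal_v(n, out):
    def m(xT):
        return float(xT[out])

    def dm(xT):
        g = np.zeros(2 * n)
        g[out] = 1.0
        return g

    return LossSpec(terminal=m, dm_dx=dm)


class TestForward:
    def test_constant_current_spike_times_match_closed_form(self):
        I = 1.6
        s = LIFSystem(1, I_bias=I)
        traj = forward_hybrid(s, 60e-6, DT)
        t_star = -s.tau_m * np.log(1 - (s.V_T - s.V_L) / (s.R * I))
        times = [e.time for e in traj.events]
        assert times[0] == pytest.approx(t_star, rel=1e-4)
        # subsequent interspike intervals equal the first-passage time too
        isis = np.diff(times)
        assert np.allclose(isis, t_star, rtol=1e-4)

    def test_subthreshold_input_gives_no_events(self):
        s = LIFSystem(1, I_bias=0.9)
        traj = forward_hybrid(s, 80e-6, DT)
        assert traj.events == []

    def test_current_jumps_equal_weight_column(self):
        W = np.array([[0.0, 0.6], [0.8, 0.0]])
        s = LIFSystem(2, W=W, I_stim=lambda t: np.array([1.8, 1.7]))
        traj = forward_hybrid(s, 50e-6, DT)
        assert traj.events
        for rec in traj.events:
            i = rec.meta["neuron"]
            jump = rec.x_plus[2:] - rec.x_minus[2:]
            np.testing.assert_allclose(jump, W[:, i], atol=1e-15)

    def test_event_budget_guard(self):
        s = LIFSystem(1, I_bias=5.0)
        with pytest.raises(RuntimeError, match="event budget"):
            forward_hybrid(s, 100e-6, DT, max_events=3)


class TestEventTimeDerivative:
    def test_dt_dI_matches_differentiated_closed_form(self):
        I = 1.6
        s = LIFSystem(1, I_bias=I)
        traj = forward_hybrid(s, 15e-6, DT)
        rec = traj.events[0]
        t_star = rec.time
        # closed form: t* = -tau ln(1 - VT/(R I));  dt*/dI analytic
        dt_dI_ref = -s.tau_m * s.V_T / (I * (s.R * I - s.V_T))
        # sensitivity of the pre-event state to I: dV/dI = R(1 - e^(-t/tau))
        dx_dI = np.array([s.R * (1 - np.exp(-t_star / s.tau_m)), 0.0])
        dt_dx, dt_dI = event_time_derivative(rec, s, dxminus_dq=dx_dI)
        assert dt_dI == pytest.approx(dt_dI_ref, rel=1e-6)
        # dt*/dx- has the declared single-entry sparsity
        assert dt_dx[1] == 0.0
        assert dt_dx[0] < 0.0  # higher V- -> earlier spike

    def test_uninvolved_state_has_zero_derivative(self):
        W = np.zeros((2, 2))
        s = LIFSystem(2, W=W, I_stim=lambda t: np.array([1.8, 0.0]))
        traj = forward_hybrid(s, 15e-6, DT)
        rec = traj.events[0]
        dt_dx, _ = event_time_derivative(rec, s)
        # only the crossing neuron's V enters the jump condition
        nz = np.nonzero(dt_dx)[0]
        assert list(nz) == [0]

    def test_grazing_event_raises(self):
        s = LIFSystem(1, I_bias=1.6)
        traj = forward_hybrid(s, 15e-6, DT)
        rec = traj.events[0]
        rec.denom = 1e-12
        with pytest.raises(GrazingEventError):
            event_time_derivative(rec, s)

    def test_excitatory_weight_advances_postsynaptic_spike(self):
        # dt*/dW < 0: stronger afferent weight -> earlier spike; the sign is
        # checked against central finite differences of the spike time
        def spike_time(w):
            W = np.array([[0.0, 0.0], [w, 0.0]])
            s = LIFSystem(2, W=W, I_stim=lambda t: np.array([1.8, 1.05]))
            traj = forward_hybrid(s, 60e-6, DT)
            t1 = [e.time for e in traj.events if e.meta.get("neuron") == 1]
            return t1[0]

        eps = 1e-3
        d = (spike_time(0.5 + eps) - spike_time(0.5 - eps)) / (2 * eps)
        assert d < 0


class TestBackwardAdjoint:
    def test_smooth_linear_system_matches_analytic_gradient(self):
        # no events: loss = V(T); dL/dV_L has the closed form of the
        # charging solution V(T) = V_L (1 - e^(-T/tau)) (x0 = 0, I = 0)
        s = LIFSystem(1, V_L=0.4, I_bias=0.0, V_T=10.0, V0=np.zeros(1))
        T = 40e-6
        traj = forward_hybrid(s, T, DT)
        assert traj.events == []
        res = backward_adjoint(s, traj, terminal_v(1, 0))
        iVL = 2  # [tau_m, tau_s, V_L, R, I_bias]
        expected = 1 - np.exp(-T / s.tau_m)
        assert res.grad[iVL] == pytest.approx(expected, rel=1e-8)

    def test_weight_without_presynaptic_spike_has_zero_gradient(self):
        W = np.array([[0.0, 0.0], [0.7, 0.0]])
        s = LIFSystem(2, W=W, I_stim=lambda t: np.array([1.8, 0.0]))
        T = 60e-6
        traj = forward_hybrid(s, T, DT)
        spiking = {e.meta["neuron"] for e in traj.events}
        assert spiking == {0}
        res = backward_adjoint(s, traj, terminal_v(2, 1))
        gW = res.grad[5:9].reshape(2, 2)
        # neuron 1 never spikes: column 1 of W accumulates exactly nothing
        np.testing.assert_array_equal(gW[:, 1], 0.0)
        assert gW[1, 0] != 0.0

    def test_three_neuron_chain_matches_finite_differences(self):
        W = np.zeros((3, 3))
        W[1, 0] = 0.9
        W[2, 1] = 0.8
        s = LIFSystem(3, W=W, I_stim=lambda t: np.array([1.8, 0.0, 0.0]))
        T = 60e-6
        loss = terminal_v(3, 2)
        traj = forward_hybrid(s, T, DT)
        assert 2 <= len(traj.events) <= 20
        adj = backward_adjoint(s, traj, loss)
        fd = finite_difference_gradient(s, loss, T, DT, eps=3e-6)
        skip = set(fd.flags["event_count_changed"])
        scale = np.abs(fd.grad).max()
        for i in range(fd.grad.size):
            if i in skip:
                continue
            assert adj.grad[i] == pytest.approx(fd.grad[i], rel=1e-3,
                                                abs=1e-3 * scale)

    def test_sparse_observations_recover_perturbed_leak(self):
        # generate 10 scalar V observations from the true model, perturb
        # V_L, and recover it by gradient descent on the observation loss
        n = 1
        true = LIFSystem(n, V_L=0.30, I_bias=0.5, V_T=10.0)
        T = 50e-6
        traj = forward_hybrid(true, T, DT)
        P = np.array([[1.0, 0.0]])
        t_obs = np.linspace(5e-6, 45e-6, 10)
        obs = [(t, P @ traj.interpolate(t), P) for t in t_obs]
        loss = LossSpec(observations=obs)

        fit = LIFSystem(n, V_L=0.40, I_bias=0.5, V_T=10.0)
        iVL, lr = 2, 0.05
        for _ in range(60):
            tr = forward_hybrid(fit, T, DT)
            g = backward_adjoint(fit, tr, loss).grad
            p = fit.get_params()
            p[iVL] -= lr * g[iVL]
            fit.set_params(p)
        assert fit.V_L == pytest.approx(true.V_L, rel=0.05)

    def test_composed_subsystems_chain_rule(self):
        # subsystem A feeds subsystem B only through events; the joint
        # adjoint gradient equals the composition of per-subsystem passes
        T = 60e-6
        WA = np.zeros((1, 1))
        stimA = lambda t: np.array([1.8])

        def joint():
            W = np.zeros((2, 2))
            W[1, 0] = 0.9
            s = LIFSystem(2, W=W, I_stim=lambda t: np.array([1.8, 0.0]))
            traj = forward_hybrid(s, T, DT)
            res = backward_adjoint(s, traj, terminal_v(2, 1))
            return res.grad

    # chained: run A alone, feed its spike times to B as inputs,
    # backprop through B (dL/dW_in, dL/dt_in), then seed A's events
        A = LIFSystem(1, W=WA, I_stim=stimA)
        trajA = forward_hybrid(A, T, DT)
        spikesA = [e.time for e in trajA.events]

        B = LIFSystem(1, W=np.zeros((1, 1)),
                      W_in=np.array([[0.9]]),
                      input_spikes=[(t, 0) for t in spikesA])
        trajB = forward_hybrid(B, T, DT)
        resB = backward_adjoint(B, trajB, terminal_v(1, 0),
                                want_event_time_grads=True)
        # B's external input events correspond 1:1, in time order, to A's
        # own spikes; their dL/dt values seed A's adjoint pass
        ext_grads = [g for g, rec in zip(resB.event_time_grads, trajB.events)
                     if rec.condition is None]
        seeds = dict(enumerate(ext_grads))
        resA = backward_adjoint(A, trajA, LossSpec(), event_time_seeds=seeds)

        g_joint = joint()
        # flow parameters are shared: the joint gradient is the sum of the
        # per-subsystem contributions
        chained_flow = resA.grad[:5] + resB.grad[:5]
        scale = np.abs(g_joint[:5]).max()
        np.testing.assert_allclose(chained_flow, g_joint[:5],
                                   rtol=1e-5, atol=1e-6 * scale)
        # B's input-weight gradient equals the joint coupling-weight one
        iW_in_B = 5 + 1  # B: 5 flow + 1 W entry, then W_in
        i_joint_W10 = 5 + 2  # joint W.ravel()[2] = W[1, 0]
        assert resB.grad[iW_in_B] == pytest.approx(
            g_joint[i_joint_W10], rel=1e-5)


class TestFiniteDifferenceOracle:
    def test_quadratic_loss_on_linear_ode(self):
        s = LIFSystem(1, V_L=0.5, I_bias=0.0, V_T=10.0, V0=np.zeros(1))
        T = 30e-6

        def m(xT):
            return float(xT[0] ** 2)

        loss = LossSpec(terminal=m)
        fd = finite_difference_gradient(s, loss, T, DT, eps=1e-5)
        VT_ = s.V_L * (1 - np.exp(-T / s.tau_m))
        dV_dVL = 1 - np.exp(-T / s.tau_m)
        assert fd.grad[2] == pytest.approx(2 * VT_ * dV_dVL, rel=1e-4)

    def test_richardson_ratio_shows_second_order(self):
        s = LIFSystem(1, V_L=0.5, I_bias=0.0, V_T=10.0, V0=np.zeros(1))
        T = 30e-6

        def m(xT):
            return float(np.cos(5 * xT[0]))

        loss = LossSpec(terminal=m)
        g1 = finite_difference_gradient(s, loss, T, DT, eps=4e-3).grad[2]
        g2 = finite_difference_gradient(s, loss, T, DT, eps=2e-3).grad[2]
        g_ref = finite_difference_gradient(s, loss, T, DT, eps=1e-4).grad[2]
        ratio = abs(g1 - g_ref) / abs(g2 - g_ref)
        assert ratio == pytest.approx(4.0, rel=0.35)

    def test_event_count_change_flagged(self):
        s = LIFSystem(1, I_bias=1.0001)  # barely suprathreshold at V_T=1
        loss = terminal_v(1, 0)
        fd = finite_difference_gradient(s, loss, 120e-6, DT, eps=1e-3)
        assert 4 in fd.flags["event_count_changed"]  # I_bias coordinate


class TestOracleSuite:
    def test_all_fixtures_agree_with_finite_differences(self):
        rows = run_gradcheck(rtol=1e-3)
        assert len(rows) >= 5
        events = [r["n_events"] for r in rows]
        assert min(events) == 0 and max(events) >= 5
        for r in rows:
            assert r["passed"], r
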