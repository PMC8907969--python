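"""Event-based adjoint gradients for hybrid dynamical systems.

Spiking networks are hybrid dynamical systems: smooth flows
``dx/dt = f(x, p, t)`` punctuated by state jumps ``x+ = T_r(x-, p, t)``
triggered when a jump condition ``j_r(x, p, t)`` crosses zero (a membrane
reaching threshold).  Loss gradients are computed by a reverse-time
adjoint pass:

* between events the adjoint satisfies ``dlam/dt = -J^T lam - (dl/dx)^T``
  with ``J`` the (sparse, block-structured) flow Jacobian;
* at each event the adjoint is propagated through the transition by the
  total derivative of the post-event state with respect to the pre-event
  state, ``D = dT/dx + (f+ - dT/dx f-) (dj/dx)^T / (dj/dx . f- + dj/dt)``,
  obtained from the implicit-function-theorem derivative of the event time
  (transversality denominator checked; tangential "grazing" crossings are
  flagged, not smoothed);
* parameters that only enter the transitions (synaptic weights) accumulate
  gradient contributions exclusively at events, while flow parameters
  accumulate ``int lam^T df/dp dt`` continuously;
* temporally sparse observations contribute Dirac terms
  ``2 P^T (P x(t_i) - xhat_i)`` to the adjoint at the observation times.

Forward and backward use the same fixed-step scheme (classical RK4 with
event times located by bisection inside the step) on the same stored
grid, so the adjoint gradient can be validated coordinate-wise against a
central finite-difference oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "JumpCondition",
    "Transition",
    "HybridSystem",
    "LIFSystem",
    "EventRecord",
    "LossSpec",
    "Trajectory",
    "GradientResult",
    "forward_hybrid",
    "event_time_derivative",
    "backward_adjoint",
    "finite_difference_gradient",
    "run_gradcheck",
    "gradcheck_fixtures",
]

EPS_GRAZE = 1e-9


class GrazingEventError(RuntimeError):
    """Raised when an event is tangential and its time derivative undefined."""


@dataclass
class JumpCondition:
    """Scalar condition j(x, t) whose upward zero crossing triggers a jump."""

    value: Callable[[np.ndarray, float], float]
    dj_dx: Callable[[np.ndarray, float], np.ndarray]
    dj_dt: Callable[[np.ndarray, float], float] | None = None


@dataclass
class Transition:
    """State map x+ = T(x-) with its Jacobian and parameter-grad hook."""

    apply: Callable[[np.ndarray, float], np.ndarray]
    dT_dx: Callable[[np.ndarray, float], np.ndarray]
    # hook(lam_plus, record, grads) accumulates transition-parameter grads
    param_grad: Callable | None = None
    meta: dict = field(default_factory=dict)


@dataclass
class EventRecord:
    """One forward event: time, condition index, states and flows around it."""

    time: float
    condition: int | None          # None for externally scheduled events
    x_minus: np.ndarray
    x_plus: np.ndarray
    f_minus: np.ndarray
    f_plus: np.ndarray
    denom: float | None = None     # transversality denominator dj/dx.f- + dj/dt
    grazing: bool = False
    sample_plus_index: int = -1    # index of the (t*, x+) sample in the grid
    meta: dict = field(default_factory=dict)


@dataclass
class LossSpec:
    """Integral + terminal + sparse-observation loss.

    ``observations`` is a list of ``(t_i, xhat_i, P)`` contributing
    ``|P x(t_i) - xhat_i|^2``; observation times are snapped to the stored
    grid.
    """

    integrand: Callable[[np.ndarray, float], float] | None = None
    dl_dx: Callable[[np.ndarray, float], np.ndarray] | None = None
    terminal: Callable[[np.ndarray], float] | None = None
    dm_dx: Callable[[np.ndarray], np.ndarray] | None = None
    observations: list[tuple[float, np.ndarray, np.ndarray]] = field(
        default_factory=list
    )


class Trajectory:
    """Dense forward trajectory plus exact event records.

    ``times``/``states`` contain the grid samples with each event inserted
    twice, as ``(t*, x-)`` immediately followed by ``(t*, x+)``, so every
    interval between consecutive samples is smooth.
    """

    def __init__(self, times, states, events, T, dt):
        self.times = np.asarray(times)
        self.states = np.asarray(states)
        self.events: list[EventRecord] = events
        self.T = T
        self.dt = dt

    def interpolate(self, t: float) -> np.ndarray:
        k = int(np.searchsorted(self.times, t, side="right")) - 1
        k = max(0, min(k, len(self.times) - 2))
        t0, t1 = self.times[k], self.times[k + 1]
        if t1 == t0:
            return self.states[k + 1].copy()
        a = (t - t0) / (t1 - t0)
        return (1 - a) * self.states[k] + a * self.states[k + 1]


class HybridSystem:
    """Generic hybrid dynamical system with a flat parameter vector.

    Subclasses define the flow ``f``, its Jacobian, the flow-parameter
    sensitivity ``df_dp``, the jump conditions with their transitions, and
    externally scheduled events.  ``get_params``/``set_params``/
    ``grad_template`` define a flat parameter layout shared by the adjoint
    and the finite-difference oracle.
    """

    n_states: int = 0

    def f(self, x: np.ndarray, t: float) -> np.ndarray:
        raise NotImplementedError

    def jac(self, x: np.ndarray, t: float) -> np.ndarray:
        raise NotImplementedError

    def df_dp(self, x: np.ndarray, t: float) -> np.ndarray:
        """(n_states, n_flow_params) sensitivity of f to the flow params."""
        raise NotImplementedError

    @property
    def jumps(self) -> list[tuple[JumpCondition, Transition]]:
        return []

    def external_events(self) -> list[tuple[float, Transition]]:
        return []

    def x0(self) -> np.ndarray:
        raise NotImplementedError

    def get_params(self) -> np.ndarray:
        raise NotImplementedError

    def set_params(self, p: np.ndarray) -> None:
        raise NotImplementedError

    def n_flow_params(self) -> int:
        raise NotImplementedError


def _rk4(f, x, t, h):
    k1 = f(x, t)
    k2 = f(x + 0.5 * h * k1, t + 0.5 * h)
    k3 = f(x + 0.5 * h * k2, t + 0.5 * h)
    k4 = f(x + h * k3, t + h)
    return x + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)


def forward_hybrid(
    sys: HybridSystem,
    T: float,
    dt: float,
    x0: np.ndarray | None = None,
    max_events: int = 10**6,
) -> Trajectory:
    """Integrate a hybrid system over [0, T] with exact event records.

    Piecewise RK4 at fixed step ``dt``; within a step an upward zero
    crossing of a jump condition is located by bisection on the sub-step,
    the transition applied atomically, and integration resumed from the
    event time.  Externally scheduled events are breakpoints of the grid.
    Simultaneously satisfied conditions are processed in ascending
    condition-index order.
    """
    x = (sys.x0() if x0 is None else np.asarray(x0, dtype=float)).copy()
    n_steps = int(round(T / dt))
    grid = list(np.arange(1, n_steps + 1) * dt)
    ext = sorted(sys.external_events(), key=lambda e: e[0])
    breaks = sorted(set(grid) | {t for t, _ in ext if 0.0 < t <= T})
    ext_iter = {}
    for t_e, tr in ext:
        ext_iter.setdefault(t_e, []).append(tr)

    times = [0.0]
    states = [x.copy()]
    events: list[EventRecord] = []
    jumps = sys.jumps
    t = 0.0

    def step_to(x, t, t_target):
        """Advance from t to t_target handling internal events."""
        nonlocal events
        while t_target - t > 1e-9 * dt:
            h = t_target - t
            j_now = [jc.value(x, t) for jc, _ in jumps]
            x_prop = _rk4(sys.f, x, t, h)
            crossed = [
                r for r, (jc, _) in enumerate(jumps)
                if j_now[r] < 0.0 and jc.value(x_prop, t + h) >= 0.0
            ]
            if not crossed:
                return x_prop, t_target
            # earliest crossing via bisection on the sub-step
            best_theta, best_r = None, None
            for r in crossed:
                jc = jumps[r][0]
                lo, hi = 0.0, 1.0
                for _ in range(60):
                    mid = 0.5 * (lo + hi)
                    if jc.value(_rk4(sys.f, x, t, h * mid), t + h * mid) >= 0.0:
                        hi = mid
                    else:
                        lo = mid
                theta = hi
                if best_theta is None or theta < best_theta:
                    best_theta, best_r = theta, r
            t_star = t + h * best_theta
            x_minus = _rk4(sys.f, x, t, h * best_theta)
            jc, tr = jumps[best_r]
            f_minus = sys.f(x_minus, t_star)
            djx = jc.dj_dx(x_minus, t_star)
            djt = jc.dj_dt(x_minus, t_star) if jc.dj_dt else 0.0
            denom = float(djx @ f_minus + djt)
            x_plus = tr.apply(x_minus, t_star)
            f_plus = sys.f(x_plus, t_star)
            times.append(t_star)
            states.append(x_minus.copy())
            times.append(t_star)
            states.append(x_plus.copy())
            rec = EventRecord(
                time=t_star, condition=best_r, x_minus=x_minus.copy(),
                x_plus=x_plus.copy(), f_minus=f_minus, f_plus=f_plus,
                denom=denom, grazing=abs(denom) < EPS_GRAZE,
                sample_plus_index=len(times) - 1,
                meta=dict(tr.meta),
            )
            events.append(rec)
            if len(events) > max_events:
                raise RuntimeError("event budget exceeded (runaway spiking?)")
            x, t = x_plus, t_star
        return x, t_target

    for t_b in breaks:
        x, t = step_to(x, t, t_b)
        if t_b in ext_iter:
            for tr in ext_iter[t_b]:
                x_minus = x.copy()
                f_minus = sys.f(x_minus, t_b)
                x = tr.apply(x_minus, t_b)
                f_plus = sys.f(x, t_b)
                times.append(t_b)
                states.append(x_minus)
                times.append(t_b)
                states.append(x.copy())
                events.append(
                    EventRecord(
                        time=t_b, condition=None, x_minus=x_minus,
                        x_plus=x.copy(), f_minus=f_minus, f_plus=f_plus,
                        sample_plus_index=len(times) - 1,
                        meta=dict(tr.meta),
                    )
                )
        else:
            times.append(t_b)
            states.append(x.copy())
    return Trajectory(times, states, events, T, dt)


def event_time_derivative(
    rec: EventRecord,
    sys: HybridSystem,
    dxminus_dq: np.ndarray | None = None,
    djdp_dq: float = 0.0,
):
    """Implicit-function-theorem derivatives of an event time.

    Returns ``(dt_dxminus, dt_dq)`` where ``dt_dxminus = -dj/dx / denom``
    and, when the sensitivity ``dx-/dq`` of the pre-event state to a scalar
    parameter q is supplied,
    ``dt_dq = -(dj/dx . dx-/dq + dj/dp . dp/dq) / denom``.
    Raises :class:`GrazingEventError` when the transversality denominator
    is below the grazing tolerance.
    """
    if rec.condition is None:
        raise ValueError("externally scheduled events have no implicit time")
    jc = sys.jumps[rec.condition][0]
    djx = jc.dj_dx(rec.x_minus, rec.time)
    denom = rec.denom
    if denom is None or abs(denom) < EPS_GRAZE:
        raise GrazingEventError(f"grazing event at t={rec.time}")
    dt_dx = -djx / denom
    dt_dq = None
    if dxminus_dq is not None:
        dt_dq = float(-(djx @ dxminus_dq + djdp_dq) / denom)
    return dt_dx, dt_dq


@dataclass
class GradientResult:
    grad: np.ndarray
    flags: dict = field(default_factory=dict)
    event_time_grads: list[float] = field(default_factory=list)


def evaluate_loss(traj: Trajectory, loss: LossSpec) -> float:
    """Loss value from a stored trajectory (trapezoid on the sample grid)."""
    L = 0.0
    ts, xs = traj.times, traj.states
    if loss.integrand is not None:
        vals = np.array([loss.integrand(x, t) for t, x in zip(ts, xs)])
        L += float(np.sum(0.5 * (vals[1:] + vals[:-1]) * np.diff(ts)))
    if loss.terminal is not None:
        L += float(loss.terminal(xs[-1]))
    for t_i, xhat, P in loss.observations:
        r = P @ traj.interpolate(t_i) - xhat
        L += float(r @ r)
    return L


def backward_adjoint(
    sys: HybridSystem,
    traj: Trajectory,
    loss: LossSpec,
    want_event_time_grads: bool = False,
    event_time_seeds: dict[int, float] | None = None,
) -> GradientResult:
    """Reverse-time adjoint pass over a stored forward trajectory.

    Integrates ``dlam/dt = -J^T lam - (dl/dx)^T`` backward between events
    with the same RK4 scheme (states linearly interpolated on the stored
    grid), applies the adjoint event transition ``lam- = D^T lam+`` at each
    event, accumulates transition-parameter gradients event-wise and
    flow-parameter gradients continuously, and adds the sparse-observation
    Dirac terms.  Returns the gradient in the system's flat parameter
    layout.

    ``event_time_seeds`` maps forward-event indices to externally supplied
    loss sensitivities dL/dt* of that event's time (the chain-rule hook for
    composing adjoint passes across event-coupled subsystems);
    ``want_event_time_grads`` reports dL/dt for externally scheduled input
    events.
    """
    ts, xs = traj.times, traj.states
    M = len(ts) - 1
    n_flow = sys.n_flow_params()
    grads: dict = {"flow": np.zeros(n_flow)}
    flags: dict = {"grazing_events": 0}

    lam = (
        np.asarray(loss.dm_dx(xs[-1]), dtype=float)
        if loss.dm_dx is not None
        else np.zeros(sys.n_states)
    )

    # snap observations onto sample times (nearest), latest first
    obs = []
    for t_i, xhat, P in loss.observations:
        k = int(np.argmin(np.abs(ts - t_i)))
        obs.append((k, np.asarray(xhat, float), np.asarray(P, float)))
    obs.sort(key=lambda o: o[0], reverse=True)
    obs_ix = 0

    def obs_jump(k):
        nonlocal lam, obs_ix
        while obs_ix < len(obs) and obs[obs_ix][0] == k:
            _, xhat, P = obs[obs_ix]
            lam = lam + 2.0 * P.T @ (P @ xs[k] - xhat)
            obs_ix += 1

    obs_jump(M)

    ev_by_plus_index = {rec.sample_plus_index: rec for rec in traj.events}
    ev_index = {id(rec): i for i, rec in enumerate(traj.events)}
    seeds = event_time_seeds or {}
    event_time_grads: dict[int, float] = {}

    def dl_dx(x, t):
        if loss.dl_dx is None:
            return np.zeros(sys.n_states)
        return np.asarray(loss.dl_dx(x, t), dtype=float)

    k = M
    while k >= 1:
        t_hi, t_lo = ts[k], ts[k - 1]
        if t_hi == t_lo:
            rec = ev_by_plus_index.get(k)
            if rec is None:
                # zero-width non-event interval (duplicate grid sample)
                k -= 1
                continue
            # transition pair: xs[k-1] = x-, xs[k] = x+
            lam_plus = lam
            if rec.condition is None:
                # externally timed event: D = dT/dx
                tr = rec.meta.get("_transition")
                dT = tr.dT_dx(rec.x_minus, rec.time) if tr is not None else np.eye(sys.n_states)
                lam = dT.T @ lam_plus
                if tr is not None and tr.param_grad is not None:
                    tr.param_grad(lam_plus, rec, grads)
                if want_event_time_grads:
                    g = float(lam_plus @ (dT @ rec.f_minus - rec.f_plus))
                    event_time_grads[id(rec)] = g
                    rec.meta["dL_dt"] = g
            else:
                jc, tr = sys.jumps[rec.condition]
                rec_dT = tr.dT_dx(rec.x_minus, rec.time)
                if rec.grazing:
                    flags["grazing_events"] += 1
                    lam = rec_dT.T @ lam_plus
                else:
                    djx = jc.dj_dx(rec.x_minus, rec.time)
                    # D = dT/dx + (f+ - dT/dx f-) (dj/dx)^T / denom, the
                    # total derivative of the post-event state w.r.t. the
                    # pre-event state through the implicit event time
                    corr = rec.f_plus - rec_dT @ rec.f_minus
                    D = rec_dT + np.outer(corr, djx) / rec.denom
                    lam = D.T @ lam_plus
                    if loss.integrand is not None:
                        # the integrand is discontinuous across the jump;
                        # the event-time shift exposes (l- - l+) dt*/dx-
                        l_m = loss.integrand(rec.x_minus, rec.time)
                        l_p = loss.integrand(rec.x_plus, rec.time)
                        lam = lam + (l_p - l_m) * djx / rec.denom
                    g_seed = seeds.get(ev_index[id(rec)])
                    if g_seed is not None:
                        # external dL/dt* seed: dt*/dx- = -dj/dx / denom
                        lam = lam - g_seed * djx / rec.denom
                if tr.param_grad is not None:
                    tr.param_grad(lam_plus, rec, grads)
            k -= 1
            continue

        # smooth interval [t_lo, t_hi]: backward RK4, cubic-Hermite state
        # interpolation, flow-parameter quadrature carried as extra states
        x_hi, x_lo = xs[k], xs[k - 1]
        h_int = t_hi - t_lo
        f_lo = sys.f(x_lo, t_lo)
        f_hi = sys.f(x_hi, t_hi)

        def x_of(t):
            a = (t - t_lo) / h_int
            h00 = (1 + 2 * a) * (1 - a) ** 2
            h10 = a * (1 - a) ** 2
            h01 = a * a * (3 - 2 * a)
            h11 = a * a * (a - 1)
            return (h00 * x_lo + h01 * x_hi
                    + h_int * (h10 * f_lo + h11 * f_hi))

        def aug_dot(y, t):
            l = y[: sys.n_states]
            x = x_of(t)
            dl = -(sys.jac(x, t).T @ l + dl_dx(x, t))
            dg = -(sys.df_dp(x, t).T @ l)   # G(t) = int_t^T df_dp^T lam
            return np.concatenate([dl, dg])

        y = np.concatenate([lam, np.zeros(n_flow)])
        y = _rk4(aug_dot, y, t_hi, t_lo - t_hi)
        lam = y[: sys.n_states]
        grads["flow"] += y[sys.n_states:]
        k -= 1
        obs_jump(k)

    grad_flat = sys.assemble_grad(grads)
    if flags["grazing_events"]:
        flags["unreliable"] = True
    res = GradientResult(grad=grad_flat, flags=flags)
    if want_event_time_grads:
        res.event_time_grads = [
            rec.meta.get("dL_dt", 0.0) for rec in traj.events
        ]
    return res


def finite_difference_gradient(
    sys: HybridSystem,
    loss: LossSpec,
    T: float,
    dt: float,
    eps: float | np.ndarray = 1e-6,
    x0: np.ndarray | None = None,
) -> GradientResult:
    """Central finite-difference gradient oracle on the same fixed grid.

    Coordinates whose perturbation changes the event count are flagged as
    non-differentiable at this point.
    """
    p0 = sys.get_params().copy()
    n_ev0 = len(forward_hybrid(sys, T, dt, x0=x0).events)
    g = np.zeros_like(p0)
    flagged = []
    scales = (
        sys.param_scales()
        if hasattr(sys, "param_scales")
        else np.maximum(np.abs(p0), 1.0)
    )
    eps_vec = np.broadcast_to(np.asarray(eps, dtype=float), p0.shape).copy()
    for i in range(p0.size):
        e = eps_vec[i] * max(scales[i], abs(p0[i]))
        vals = []
        counts = []
        for s in (+1, -1):
            p = p0.copy()
            p[i] += s * e
            sys.set_params(p)
            traj = forward_hybrid(sys, T, dt, x0=x0)
            counts.append(len(traj.events))
            vals.append(evaluate_loss(traj, loss))
        g[i] = (vals[0] - vals[1]) / (2 * e)
        if counts[0] != n_ev0 or counts[1] != n_ev0:
            flagged.append(i)
    sys.set_params(p0)
    return GradientResult(grad=g, flags={"event_count_changed": flagged})


# ---------------------------------------------------------------------------
# Reference instance: network of LIF neurons
# ---------------------------------------------------------------------------


class LIFSystem(HybridSystem):
    """N current-based LIF neurons as a hybrid system.

    State ``x = (V_1..V_N, I_1..I_N)`` with flows::

        tau_m dV/dt = (V_L - V) + R (I + I_stim(t) + I_bias)
        tau_s dI/dt = -I

    Threshold crossing of neuron i (``V_i = V_T``) resets ``V_i`` to
    ``V_reset`` and jumps the synaptic currents by column i of the weight
    matrix, ``I+ = I- + W e_i``.  Optional externally scheduled input
    spikes jump ``I`` by a column of ``W_in``.  The flat parameter vector
    is ``[tau_m, tau_s, V_L, R, I_bias] + W.ravel() + W_in.ravel()``.
    """

    FLOW_NAMES = ("tau_m", "tau_s", "V_L", "R", "I_bias")

    def __init__(
        self,
        n: int,
        W: np.ndarray | None = None,
        tau_m: float = 10e-6,
        tau_s: float = 5e-6,
        V_L: float = 0.0,
        R: float = 1.0,
        I_bias: float = 0.0,
        V_T: float = 1.0,
        V_reset: float = 0.0,
        I_stim: Callable[[float], np.ndarray] | None = None,
        W_in: np.ndarray | None = None,
        input_spikes: Sequence[tuple[float, int]] = (),
        V0: np.ndarray | None = None,
        I0: np.ndarray | None = None,
    ):
        self.n = n
        self.n_states = 2 * n
        self.W = np.zeros((n, n)) if W is None else np.asarray(W, float).copy()
        self.tau_m, self.tau_s = float(tau_m), float(tau_s)
        self.V_L, self.R, self.I_bias = float(V_L), float(R), float(I_bias)
        self.V_T, self.V_reset = float(V_T), float(V_reset)
        self.I_stim = I_stim
        self.W_in = None if W_in is None else np.asarray(W_in, float).copy()
        self.input_spikes = list(input_spikes)
        self._V0 = np.full(n, self.V_L) if V0 is None else np.asarray(V0, float)
        self._I0 = np.zeros(n) if I0 is None else np.asarray(I0, float)
        self._build_jumps()

    # -- parameter plumbing -------------------------------------------------
    def n_flow_params(self) -> int:
        return 5

    def get_params(self) -> np.ndarray:
        parts = [
            np.array([self.tau_m, self.tau_s, self.V_L, self.R, self.I_bias]),
            self.W.ravel(),
        ]
        if self.W_in is not None:
            parts.append(self.W_in.ravel())
        return np.concatenate(parts)

    def set_params(self, p: np.ndarray) -> None:
        # the initial state is fixed at construction and does not track V_L
        self.tau_m, self.tau_s, self.V_L, self.R, self.I_bias = p[:5]
        k = 5 + self.n * self.n
        self.W = p[5:k].reshape(self.n, self.n).copy()
        if self.W_in is not None:
            self.W_in = p[k:].reshape(self.W_in.shape).copy()
        self._build_jumps()

    def param_scales(self) -> np.ndarray:
        parts = [
            np.array([self.tau_m, self.tau_s, abs(self.V_T), 1.0, 1.0]),
            np.full(self.n * self.n, 1.0),
        ]
        if self.W_in is not None:
            parts.append(np.full(self.W_in.size, 1.0))
        return np.abs(np.concatenate(parts))

    def assemble_grad(self, grads: dict) -> np.ndarray:
        parts = [grads["flow"], grads.get("W", np.zeros_like(self.W)).ravel()]
        if self.W_in is not None:
            parts.append(grads.get("W_in", np.zeros_like(self.W_in)).ravel())
        return np.concatenate(parts)

    # -- dynamics -----------------------------------------------------------
    def x0(self) -> np.ndarray:
        return np.concatenate([self._V0, self._I0])

    def _stim(self, t: float) -> np.ndarray:
        s = np.zeros(self.n) if self.I_stim is None else np.asarray(self.I_stim(t))
        return s + self.I_bias

    def f(self, x: np.ndarray, t: float) -> np.ndarray:
        V, I = x[: self.n], x[self.n:]
        dV = (self.V_L - V + self.R * (I + self._stim(t))) / self.tau_m
        dI = -I / self.tau_s
        return np.concatenate([dV, dI])

    def jac(self, x: np.ndarray, t: float) -> np.ndarray:
        n = self.n
        J = np.zeros((2 * n, 2 * n))
        J[:n, :n] = -np.eye(n) / self.tau_m
        J[:n, n:] = self.R * np.eye(n) / self.tau_m
        J[n:, n:] = -np.eye(n) / self.tau_s
        return J

    def df_dp(self, x: np.ndarray, t: float) -> np.ndarray:
        n = self.n
        V, I = x[: self.n], x[self.n:]
        dV = (self.V_L - V + self.R * (I + self._stim(t))) / self.tau_m
        out = np.zeros((2 * n, 5))
        out[:n, 0] = -dV / self.tau_m                        # d/d tau_m
        out[n:, 1] = I / self.tau_s**2                       # d/d tau_s
        out[:n, 2] = 1.0 / self.tau_m                        # d/d V_L
        out[:n, 3] = (I + self._stim(t)) / self.tau_m        # d/d R
        out[:n, 4] = self.R / self.tau_m                     # d/d I_bias
        return out

    # -- events -------------------------------------------------------------
    def _build_jumps(self) -> None:
        n = self.n
        jumps = []
        for i in range(n):
            def jv(x, t, i=i):
                return float(x[i] - self.V_T)

            def jdx(x, t, i=i):
                g = np.zeros(2 * n)
                g[i] = 1.0
                return g

            def tapply(x, t, i=i):
                y = x.copy()
                y[i] = self.V_reset
                y[n:] = y[n:] + self.W[:, i]
                return y

            def tdx(x, t, i=i):
                D = np.eye(2 * n)
                D[i, i] = 0.0
                return D

            def pgrad(lam_plus, rec, grads, i=i):
                gW = grads.setdefault("W", np.zeros_like(self.W))
                gW[:, i] += lam_plus[n:]

            jumps.append(
                (
                    JumpCondition(value=jv, dj_dx=jdx),
                    Transition(apply=tapply, dT_dx=tdx, param_grad=pgrad,
                               meta={"neuron": i}),
                )
            )
        self._jumps = jumps

    @property
    def jumps(self):
        return self._jumps

    def external_events(self):
        n = self.n
        evs = []
        for t_s, src in self.input_spikes:
            def apply(x, t, src=src):
                y = x.copy()
                y[n:] = y[n:] + self.W_in[:, src]
                return y

            def dT_dx(x, t):
                return np.eye(2 * n)

            def pgrad(lam_plus, rec, grads, src=src):
                g = grads.setdefault("W_in", np.zeros_like(self.W_in))
                g[:, src] += lam_plus[n:]

            tr = Transition(apply=apply, dT_dx=dT_dx, param_grad=pgrad,
                            meta={"input": src, "time": t_s})
            tr.meta["_transition"] = tr
            evs.append((t_s, tr))
        return evs


# ---------------------------------------------------------------------------
# Oracle suite
# ---------------------------------------------------------------------------


def _terminal_vout(n: int, out: int) -> LossSpec:
    def m(xT):
        return float(xT[out])

    def dm(xT):
        g = np.zeros(2 * n)
        g[out] = 1.0
        return g

    return LossSpec(terminal=m, dm_dx=dm)


def _integral_v2(n: int) -> LossSpec:
    def l(x, t):
        return float(x[:n] @ x[:n])

    def dl(x, t):
        g = np.zeros(2 * n)
        g[:n] = 2 * x[:n]
        return g

    return LossSpec(integrand=l, dl_dx=dl)


def gradcheck_fixtures() -> list[tuple[str, LIFSystem, LossSpec, float, float]]:
    """Family of small LIF hybrid systems with analytic/terminal losses.

    Each entry is ``(name, system, loss, T, dt)`` covering 1-5 neurons,
    feedforward and recurrent coupling, and 0-10 events.
    """
    fx = []
    T, dt = 60e-6, 0.05e-6

    # 1 neuron, subthreshold (0 events), integral loss
    s = LIFSystem(1, I_bias=0.5)
    fx.append(("1n_subthreshold", s, _integral_v2(1), T, dt))

    # 1 neuron, suprathreshold (several events), terminal loss on V
    s = LIFSystem(1, I_bias=1.6)
    fx.append(("1n_tonic", s, _terminal_vout(1, 0), T, dt))

    # 3 neuron feedforward chain, loss = V_out(T)
    W = np.zeros((3, 3))
    W[1, 0] = 0.9
    W[2, 1] = 0.8
    def stim3(t):
        return np.array([1.8, 0.0, 0.0])
    s = LIFSystem(3, W=W, I_stim=stim3)
    fx.append(("3n_chain", s, _terminal_vout(3, 2), T, dt))

    # 2 mutually exciting neurons (recurrent), integral loss
    W = np.array([[0.0, 0.7], [0.7, 0.0]])
    def stim2(t):
        return np.array([1.7, 0.2])
    s = LIFSystem(2, W=W, I_stim=stim2)
    fx.append(("2n_recurrent", s, _integral_v2(2), T, dt))

    # 5 neuron sparse recurrent net with input spikes, terminal loss
    rng = np.random.default_rng(7)
    W = np.where(rng.random((5, 5)) < 0.4, rng.uniform(0.2, 0.6, (5, 5)), 0.0)
    np.fill_diagonal(W, 0.0)
    W_in = rng.uniform(0.4, 0.9, (5, 2))
    spikes = [(8e-6, 0), (15e-6, 1), (22e-6, 0)]
    def stim5(t):
        return np.full(5, 0.9)
    s = LIFSystem(5, W=W, I_stim=stim5, W_in=W_in, input_spikes=spikes)
    fx.append(("5n_recurrent_inputs", s, _terminal_vout(5, 4), T, dt))

    return fx


def run_gradcheck(
    rtol: float = 1e-3, eps: float = 3e-6, verbose: bool = False
) -> list[dict]:
    """Compare adjoint and finite-difference gradients on the fixtures.

    Returns one row per fixture with the worst relative coordinate-wise
    discrepancy (excluding coordinates flagged non-differentiable by the
    oracle) and a pass/fail verdict at ``rtol``.
    """
    rows = []
    for name, sys_, loss, T, dt in gradcheck_fixtures():
        traj = forward_hybrid(sys_, T, dt)
        adj = backward_adjoint(sys_, traj, loss)
        fd = finite_difference_gradient(sys_, loss, T, dt, eps=eps)
        skip = set(fd.flags.get("event_count_changed", []))
        scale = max(1e-12, float(np.max(np.abs(fd.grad))))
        worst = 0.0
        for i in range(fd.grad.size):
            if i in skip:
                continue
            err = abs(adj.grad[i] - fd.grad[i]) / max(scale, abs(fd.grad[i]))
            worst = max(worst, err)
        rows.append(
            {
                "fixture": name,
                "n_events": len(traj.events),
                "n_params": int(fd.grad.size),
                "n_skipped": len(skip),
                "max_rel_err": worst,
                "passed": bool(worst < rtol),
            }
        )
        if verbose:
            print(rows[-1])
    return rows
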