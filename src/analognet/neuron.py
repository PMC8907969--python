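"""Adaptive exponential integrate-and-fire (AdEx) neuron dynamics.

The membrane of capacitance ``C_m`` integrates a leak current toward
``E_l``, an exponential spike-initiation current with slope ``Delta_T``
and soft threshold ``V_T``, the adaptation current ``w`` and the external
current ``I``::

    C_m dV/dt = -g_l (V - E_l) + g_l Delta_T exp((V - V_T)/Delta_T) - w + I
    tau_w dw/dt = a (V - E_l) - w

A spike is emitted when ``V`` crosses the hard threshold ``V_th``; the
membrane is then clamped to the reset potential ``V_r`` for the refractory
period ``t_r`` and ``w`` is incremented by ``b``.  Feature-enable flags
reduce the model to LIF (no exponential, no adaptation) or to a pure
charge integrator (all enables off), the operating mode used for analog
matrix multiplication.

All quantities are SI, in the accelerated hardware time domain (us-scale
time constants).  Biological parameter sets enter through
:func:`convert_biological_params`.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np

from .constants import ACCELERATION_FACTOR, DEFAULT_DT

__all__ = [
    "AdExParameters",
    "NeuronState",
    "StimulusProtocol",
    "SpikeTrain",
    "convert_biological_params",
    "step_neuron",
    "run_neuron",
    "simulate_adex_batch",
    "classify_firing_pattern",
    "ClassifierThresholds",
]


@dataclass
class AdExParameters:
    """Full parameter set of one AdEx neuron circuit (hardware time domain).

    ``V_th`` defaults to ``V_T + 5 Delta_T`` and ``I_exp_max`` (the clamp on
    the exponential current, mimicking finite circuit currents) defaults to
    ``50 g_l Delta_T``.
    """

    C_m: float = 2e-12            # F
    g_l: float = 2e-7             # S  -> tau_m = 10 us
    E_l: float = 0.40             # V
    Delta_T: float = 0.010        # V
    V_T: float = 0.52             # V, soft threshold
    V_th: float | None = None     # V, hard firing threshold
    V_r: float = 0.40             # V, reset potential
    t_r: float = 1e-6             # s, refractory period
    a: float = 0.0                # S, subthreshold adaptation (may be < 0)
    b: float = 0.0                # A, spike-triggered adaptation increment
    tau_w: float = 50e-6          # s
    enable_exp: bool = True
    enable_adapt: bool = True
    enable_leak: bool = True
    enable_threshold: bool = True
    I_exp_max: float | None = None  # A, clamp on the exponential current
    domain: str = "hardware"

    def __post_init__(self) -> None:
        if self.C_m <= 0:
            raise ValueError("C_m must be positive")
        if self.tau_w <= 0:
            raise ValueError("tau_w must be positive")
        if self.t_r < 0:
            raise ValueError("t_r must be non-negative")
        if self.V_th is None:
            self.V_th = self.V_T + 5.0 * self.Delta_T
        if self.I_exp_max is None:
            self.I_exp_max = 50.0 * self.g_l * self.Delta_T
        if self.enable_exp:
            if self.Delta_T <= 0:
                raise ValueError("Delta_T must be positive when enable_exp")
            if self.V_th <= self.V_T:
                raise ValueError("V_th must exceed V_T when enable_exp")
        if self.domain not in ("hardware", "biological"):
            raise ValueError("domain must be 'hardware' or 'biological'")

    @property
    def tau_m(self) -> float:
        """Membrane time constant C_m / g_l."""
        return self.C_m / self.g_l


@dataclass
class NeuronState:
    V: float
    w: float = 0.0
    refractory_until: float = -np.inf
    last_spike_time: float | None = None


@dataclass
class StimulusProtocol:
    """Step-current stimulus I(t) = I_0 * Theta(t - t_on) * Theta(t_off - t)."""

    I_0: float
    t_on: float = 50e-6
    t_off: float = 400e-6
    T: float = 500e-6

    def __post_init__(self) -> None:
        if not (0 <= self.t_on < self.t_off <= self.T):
            raise ValueError("require 0 <= t_on < t_off <= T")

    def current(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return np.where((t >= self.t_on) & (t < self.t_off), self.I_0, 0.0)


class SpikeTrain:
    """Strictly increasing spike times (s) of one unit."""

    def __init__(self, times: Sequence[float] = ()):  # noqa: D107
        arr = np.asarray(list(times), dtype=float)
        if arr.size > 1 and not np.all(np.diff(arr) > 0):
            raise ValueError("spike times must be strictly increasing")
        self.times = arr

    def __len__(self) -> int:
        return self.times.size

    def __iter__(self):
        return iter(self.times)

    def isis(self) -> np.ndarray:
        return np.diff(self.times)

    def restricted(self, t0: float, t1: float) -> "SpikeTrain":
        m = (self.times >= t0) & (self.times <= t1)
        return SpikeTrain(self.times[m])


def convert_biological_params(
    params_bio: AdExParameters, acceleration: float = ACCELERATION_FACTOR
) -> AdExParameters:
    """Map a biological-time parameter set into the accelerated domain.

    Time constants (``tau_w``, ``t_r`` and the derived ``tau_m``) are divided
    by the acceleration factor; voltages are unchanged.  The capacitance is
    kept (it is a physical property of the circuit) and the conductances and
    currents are scaled up instead, which transforms ``tau_m = C_m/g_l``
    identically and leaves the voltage trajectories invariant under the time
    rescaling ``t -> t/acceleration``.
    """
    if acceleration <= 0:
        raise ValueError("acceleration must be positive")
    k = acceleration
    new_domain = "hardware" if params_bio.domain == "biological" else params_bio.domain
    return replace(
        params_bio,
        g_l=params_bio.g_l * k,
        a=params_bio.a * k,
        b=params_bio.b * k,
        I_exp_max=params_bio.I_exp_max * k,
        tau_w=params_bio.tau_w / k,
        t_r=params_bio.t_r / k,
        domain=new_domain,
    )


def _exp_current(V: np.ndarray, p_gl, p_DT, p_VT, p_Imax, enable) -> np.ndarray:
    """Clamped exponential spike-initiation current (vectorised)."""
    arg = np.clip((V - p_VT) / p_DT, -100.0, 50.0)
    I = p_gl * p_DT * np.exp(arg)
    return np.where(enable, np.minimum(I, p_Imax), 0.0)


def step_neuron(
    state: NeuronState,
    params: AdExParameters,
    I_in: float,
    dt: float,
    t: float = 0.0,
) -> NeuronState:
    """One exponential-Euler update of (V, w); no threshold handling.

    The linear leak term is integrated exactly over the step while the
    exponential and adaptation currents are held at their start-of-step
    values; disabled terms contribute exactly zero.  The refractory clamp is
    honoured: while ``t < refractory_until`` the membrane stays at ``V_r``.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    V, w = state.V, state.w
    for name, val in (("V", V), ("w", w), ("I_in", I_in)):
        if not np.isfinite(val):
            raise FloatingPointError(f"non-finite value in term '{name}': {val!r}")

    I_exp = float(
        _exp_current(
            np.asarray(V), params.g_l, params.Delta_T, params.V_T,
            params.I_exp_max, params.enable_exp,
        )
    )
    w_eff = w if params.enable_adapt else 0.0
    I_other = I_exp - w_eff + I_in

    refractory = t < state.refractory_until
    if refractory:
        V_new = params.V_r
    elif params.enable_leak:
        V_inf = params.E_l + I_other / params.g_l
        V_new = V_inf + (V - V_inf) * np.exp(-dt / params.tau_m)
    else:
        V_new = V + dt * I_other / params.C_m

    if params.enable_adapt:
        w_target = params.a * (V - params.E_l)
        w_new = w_target + (w - w_target) * np.exp(-dt / params.tau_w)
    else:
        w_new = 0.0

    if not np.isfinite(V_new):
        raise FloatingPointError("membrane update overflowed (exponential term)")
    return NeuronState(
        V=float(V_new),
        w=float(w_new),
        refractory_until=state.refractory_until,
        last_spike_time=state.last_spike_time,
    )


class _ParamArrays:
    """Struct-of-arrays view of a batch of AdEx parameter sets."""

    FIELDS = (
        "C_m", "g_l", "E_l", "Delta_T", "V_T", "V_th", "V_r", "t_r",
        "a", "b", "tau_w", "I_exp_max",
    )
    FLAGS = ("enable_exp", "enable_adapt", "enable_leak", "enable_threshold")

    def __init__(self, params: Sequence[AdExParameters]):
        for f in self.FIELDS:
            setattr(self, f, np.array([getattr(p, f) for p in params], dtype=float))
        for f in self.FLAGS:
            setattr(self, f, np.array([getattr(p, f) for p in params], dtype=bool))
        self.n = len(params)
        self.tau_m = self.C_m / self.g_l


def simulate_adex_batch(
    params: Sequence[AdExParameters] | _ParamArrays,
    I_of_t: Callable[[float], np.ndarray] | np.ndarray,
    T: float,
    dt: float = DEFAULT_DT,
    V0: np.ndarray | None = None,
    record: bool = True,
):
    """Integrate a batch of independent AdEx neurons over [0, T].

    ``I_of_t`` is either a callable ``t -> (n,) current array`` or a
    pre-evaluated ``(n_steps, n)`` array.  Returns ``(t_grid, V_trace,
    w_trace, spikes)`` where ``spikes`` is a list of per-neuron spike-time
    lists.  Threshold crossings are located by linear interpolation within
    the step; the membrane is clamped to ``V_r`` for ``t_r`` afterwards and
    ``w`` is incremented by ``b``.
    """
    pa = params if isinstance(params, _ParamArrays) else _ParamArrays(params)
    n = pa.n
    n_steps = int(round(T / dt))
    t_grid = np.arange(n_steps + 1) * dt

    V = np.full(n, np.nan) if V0 is None else np.asarray(V0, dtype=float).copy()
    if V0 is None:
        V = pa.E_l.copy()
    w = np.zeros(n)
    refr_until = np.full(n, -np.inf)
    spikes: list[list[float]] = [[] for _ in range(n)]

    V_trace = np.empty((n_steps + 1, n)) if record else None
    w_trace = np.empty((n_steps + 1, n)) if record else None
    if record:
        V_trace[0] = V
        w_trace[0] = w

    pre_I = isinstance(I_of_t, np.ndarray)
    for k in range(n_steps):
        t = k * dt
        I_in = I_of_t[k] if pre_I else np.asarray(I_of_t(t), dtype=float)

        I_exp = _exp_current(V, pa.g_l, pa.Delta_T, pa.V_T, pa.I_exp_max, pa.enable_exp)
        I_other = I_exp - np.where(pa.enable_adapt, w, 0.0) + I_in

        V_inf = pa.E_l + I_other / pa.g_l
        V_leak = V_inf + (V - V_inf) * np.exp(-dt / pa.tau_m)
        V_int = V + dt * I_other / pa.C_m
        V_new = np.where(pa.enable_leak, V_leak, V_int)

        w_target = pa.a * (V - pa.E_l)
        w_new = np.where(
            pa.enable_adapt,
            w_target + (w - w_target) * np.exp(-dt / pa.tau_w),
            0.0,
        )

        # refractory clamp overrides the free update
        refr = t < refr_until
        V_new = np.where(refr, pa.V_r, V_new)

        # threshold crossings (only outside refractoriness)
        crossed = pa.enable_threshold & ~refr & (V_new >= pa.V_th) & (V < pa.V_th)
        if np.any(crossed):
            idx = np.nonzero(crossed)[0]
            frac = (pa.V_th[idx] - V[idx]) / (V_new[idx] - V[idx])
            t_star = t + frac * dt
            for j, ts in zip(idx, t_star):
                spikes[j].append(float(ts))
            V_new[idx] = pa.V_r[idx]
            w_new[idx] = w_new[idx] + pa.b[idx]
            refr_until[idx] = t_star + pa.t_r[idx]

        if not np.all(np.isfinite(V_new)):
            bad = int(np.nonzero(~np.isfinite(V_new))[0][0])
            raise FloatingPointError(
                f"membrane of neuron {bad} overflowed (exponential term)"
            )

        V = V_new
        w = w_new
        if record:
            V_trace[k + 1] = V
            w_trace[k + 1] = w

    return t_grid, V_trace, w_trace, spikes


def run_neuron(
    params: AdExParameters,
    protocol: StimulusProtocol,
    dt: float = DEFAULT_DT,
):
    """Simulate one neuron under a step-current protocol.

    Returns ``(t_grid, V_trace, w_trace, SpikeTrain)`` with traces sampled
    every ``dt``.
    """
    n_steps = int(round(protocol.T / dt))
    I = protocol.current(np.arange(n_steps) * dt)[:, None]
    t_grid, V, w, spikes = simulate_adex_batch([params], I, protocol.T, dt)
    return t_grid, V[:, 0], w[:, 0], SpikeTrain(spikes[0])


@dataclass
class ClassifierThresholds:
    """Configurable decision thresholds of the firing-pattern classifier."""

    transient_frac: float = 0.20   # spikes confined to first 20% of window
    delay_frac: float = 0.30       # first-spike latency > 30% -> delayed_*
    burst_ratio: float = 0.25      # intra-burst ISI < ratio * inter-burst ISI
    tonic_cv: float = 0.35         # max ISI coefficient of variation for tonic
    sustain_factor: float = 2.0    # last spike within factor*period of t_off


def classify_firing_pattern(
    spikes: SpikeTrain,
    protocol: StimulusProtocol,
    thresholds: ClassifierThresholds | None = None,
) -> str:
    """Deterministically label a step-response spike train.

    Labels: ``silent``, ``tonic``, ``transient``, ``initial_burst``,
    ``regular_bursting``, ``delayed_regular_bursting``, ``other``.  The
    decision rules operate on ISI statistics inside the stimulus window:
    transient responses are confined to the leading fraction of the window,
    bursting requires a bimodal ISI split recurring until stimulus offset,
    and a long first-spike latency adds the ``delayed_`` prefix.
    """
    th = thresholds or ClassifierThresholds()
    times = np.asarray(spikes.times, dtype=float)
    if times.size and (times.min() < 0 or times.max() > protocol.T):
        raise ValueError("spikes outside [0, T]")

    t_on, t_off = protocol.t_on, protocol.t_off
    window = t_off - t_on
    times = times[(times >= t_on) & (times <= t_off + 0.05 * window)]
    if times.size == 0:
        return "silent"

    latency = times[0] - t_on
    delayed = latency > th.delay_frac * window

    if times.max() <= t_on + th.transient_frac * window:
        return "transient"

    isis = np.diff(times)
    if isis.size == 0:
        return "other"

    # bimodal ISI split: widest multiplicative gap between sorted ISIs
    srt = np.sort(isis)
    label = None
    if srt[0] < th.burst_ratio * srt[-1]:
        ratios = srt[1:] / srt[:-1]
        k = int(np.argmax(ratios))
        split = float(np.sqrt(srt[k] * srt[k + 1]))
        small = isis < split
        intra_max = isis[small].max()
        inter = isis[~small]
        if inter.size and intra_max < th.burst_ratio * inter.min():
            first_large = int(np.nonzero(~small)[0][0])
            recurring = bool(np.any(small[first_large:]))
            period = float(np.median(inter))
            sustained = times.max() >= t_off - th.sustain_factor * period
            if recurring and sustained:
                label = "regular_bursting"
            elif not recurring:
                # one leading burst followed by tonic ISIs
                tail = inter
                tail_cv = np.std(tail) / np.mean(tail) if tail.size >= 2 else 0.0
                if sustained and tail_cv < th.tonic_cv:
                    label = "initial_burst"

    if label is None:
        cv = np.std(isis) / np.mean(isis) if isis.size >= 2 else 0.0
        sustained = times.max() >= t_off - th.sustain_factor * np.median(isis)
        if cv < th.tonic_cv and sustained:
            label = "tonic"

    if label is None:
        return "other"
    if delayed and label in ("regular_bursting", "tonic"):
        return "delayed_" + label if label == "regular_bursting" else label
    return label
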