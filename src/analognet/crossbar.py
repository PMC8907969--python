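"""Quantized synaptic crossbar and analog matrix-multiply (MAC) mode.

Each quadrant is a 256x128 array of synapses holding a 6-bit weight and a
6-bit source address.  An event arriving in a row carries a 6-bit label
and a 5-bit graded payload; every synapse in the row whose address matches
the label injects a charge proportional to ``weight * payload/31`` into
its column's excitatory or inhibitory synaptic current (the sign is a
per-row driver property).  Synaptic currents decay exponentially with
independent excitatory/inhibitory time constants; decay is evaluated
analytically, so the event-driven current is exact.

In MAC mode the neurons act as pure charge integrators: input vectors are
encoded as graded payloads, signed weights use an excitatory/inhibitory
row pair, the membrane deflection after all events equals a scaled matrix
product, and readout is quantized to 8 bits over a configured dynamic
range.  Larger problems are tiled into crossbar-sized blocks and the
partial results accumulated digitally at full precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import constants as C

__all__ = [
    "Synapse",
    "SynapseArray",
    "EventPacket",
    "SynapticState",
    "MACConfig",
    "deliver_event",
    "decay_currents",
    "mac_forward",
    "mac_tiled",
]


@dataclass
class Synapse:
    weight: int
    address: int

    def __post_init__(self) -> None:
        if not (0 <= self.weight <= C.WEIGHT_MAX):
            raise ValueError("weight outside 6-bit range")
        if not (0 <= self.address <= C.ADDRESS_MAX):
            raise ValueError("address outside 6-bit range")


class SynapseArray:
    """Four quadrants of 256x128 synapses with per-row driver config."""

    def __init__(
        self,
        n_quadrants: int = C.N_QUADRANTS,
        rows: int = C.ROWS_PER_QUADRANT,
        cols: int = C.COLS_PER_QUADRANT,
    ):
        self.n_quadrants = n_quadrants
        self.rows = rows
        self.cols = cols
        self.weights = np.zeros((n_quadrants, rows, cols), dtype=np.uint8)
        self.addresses = np.zeros((n_quadrants, rows, cols), dtype=np.uint8)
        # +1 excitatory, -1 inhibitory, per row
        self.row_sign = np.ones((n_quadrants, rows), dtype=np.int8)
        self.row_enabled = np.ones((n_quadrants, rows), dtype=bool)
        self.dropped_events = 0

    def set_row(self, quadrant: int, row: int, weights, addresses,
                sign: int = 1, enabled: bool = True) -> None:
        w = np.asarray(weights, dtype=np.int64)
        a = np.asarray(addresses, dtype=np.int64)
        if np.any((w < 0) | (w > C.WEIGHT_MAX)):
            raise ValueError("weight outside 6-bit range")
        if np.any((a < 0) | (a > C.ADDRESS_MAX)):
            raise ValueError("address outside 6-bit range")
        self.weights[quadrant, row, : len(w)] = w
        self.addresses[quadrant, row, : len(a)] = a
        self.row_sign[quadrant, row] = 1 if sign >= 0 else -1
        self.row_enabled[quadrant, row] = enabled


@dataclass
class EventPacket:
    """Address event: (time, quadrant, row, label, graded payload)."""

    time: float
    row: int
    label: int
    payload: int = C.PAYLOAD_MAX
    quadrant: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.label <= C.ADDRESS_MAX):
            raise ValueError("label outside 6-bit range")
        if not (0 <= self.payload <= C.PAYLOAD_MAX):
            raise ValueError("payload outside 5-bit range")


@dataclass
class SynapticState:
    """Per-neuron excitatory/inhibitory synaptic currents (A)."""

    n_neurons: int = C.COLS_PER_QUADRANT
    tau_syn_exc: float = 2e-6
    tau_syn_inh: float = 2e-6
    gamma: float = 1e-9   # charge scale, A per (unit weight * unit payload)
    I_exc: np.ndarray = field(default=None)  # type: ignore[assignment]
    I_inh: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.tau_syn_exc <= 0 or self.tau_syn_inh <= 0:
            raise ValueError("synaptic time constants must be positive")
        if self.I_exc is None:
            self.I_exc = np.zeros(self.n_neurons)
        if self.I_inh is None:
            self.I_inh = np.zeros(self.n_neurons)

    @property
    def total(self) -> np.ndarray:
        return self.I_exc - self.I_inh


def deliver_event(
    array: SynapseArray, state: SynapticState, ev: EventPacket
) -> SynapticState:
    """Deliver one labelled event to a crossbar row (address matching).

    Every synapse in the row whose stored address equals the event label
    increments its column's excitatory or inhibitory current (per the row
    driver sign) by ``gamma * weight * payload/31``; non-matching synapses
    receive exactly zero.  Events to disabled rows are dropped and counted.
    """
    q, r = ev.quadrant, ev.row
    if not array.row_enabled[q, r]:
        array.dropped_events += 1
        return state
    match = array.addresses[q, r] == ev.label
    amp = state.gamma * array.weights[q, r].astype(float) * (ev.payload / C.PAYLOAD_MAX)
    inc = np.where(match, amp, 0.0)[: state.I_exc.size]
    if array.row_sign[q, r] > 0:
        state.I_exc = state.I_exc.copy()
        state.I_exc[: inc.size] += inc
    else:
        state.I_inh = state.I_inh.copy()
        state.I_inh[: inc.size] += inc
    return state


def decay_currents(state: SynapticState, dt: float) -> SynapticState:
    """Analytic exponential decay of both currents over ``dt`` (>= 0)."""
    if dt < 0:
        raise ValueError("dt must be non-negative")
    state.I_exc = state.I_exc * np.exp(-dt / state.tau_syn_exc)
    state.I_inh = state.I_inh * np.exp(-dt / state.tau_syn_inh)
    return state


def synaptic_current_at(
    events: list[tuple[float, float]], t: float, tau: float, gamma: float = 1.0
) -> float:
    """Closed-form current sum(j) gamma * w_j * exp(-(t-t_j)/tau) for t >= t_j."""
    return float(
        sum(gamma * w * np.exp(-(t - tj) / tau) for tj, w in events if tj <= t)
    )


@dataclass
class MACConfig:
    """Scaling of the analog multiply-accumulate readout.

    ``gamma_charge`` is chosen so a full-weight, full-payload event
    deflects an integrator neuron by 1/64 of the readout dynamic range,
    keeping 64-input sums in range.
    """

    C_m: float = 2e-12              # F, integrator capacitance
    dynamic_range: float = 0.6      # V of membrane deflection at full scale
    noise_sigma: float = 0.0        # V, optional additive readout noise
    seed: int | None = None

    @property
    def gamma_charge(self) -> float:
        """Charge (C) per unit weight*payload event."""
        full_deflection = self.dynamic_range / 64.0
        return full_deflection * self.C_m / (C.WEIGHT_MAX * 1.0)

    @property
    def lsb(self) -> float:
        return self.dynamic_range / (C.CADC_LEVELS - 1)


def _encode_payloads(x: np.ndarray) -> np.ndarray:
    if np.any((x < 0) | (x > 1)):
        raise ValueError("inputs must lie in [0, 1]")
    return np.round(np.asarray(x, dtype=float) * C.PAYLOAD_MAX).astype(int)


def mac_forward(
    weights: np.ndarray,
    x: np.ndarray,
    quantize: bool = True,
    config: MACConfig | None = None,
) -> np.ndarray:
    """One crossbar pass of the analog matrix product ``W @ x``.

    ``weights`` is an (m, n) signed integer matrix in [-63, 63] with
    ``n <= 128`` signed inputs (each consumes an excitatory and an
    inhibitory row) and ``m <= 512`` output columns; ``x`` lies in [0, 1]^n
    and is encoded as 5-bit graded payloads.  The integrator neurons
    accumulate the injected charges; the membrane deflection (baseline
    subtracted) is returned in volts, quantized to the 8-bit readout grid
    when ``quantize``.
    """
    cfg = config or MACConfig()
    W = np.asarray(weights, dtype=np.int64)
    if W.ndim == 1:
        W = W[None, :]
    m, n = W.shape
    if np.any(np.abs(W) > C.WEIGHT_MAX):
        raise ValueError("weight outside signed 6-bit range")
    if n > C.COLS_PER_QUADRANT:
        raise ValueError(
            f"at most {C.COLS_PER_QUADRANT} signed inputs per pass; use mac_tiled"
        )
    if m > C.N_NEURONS:
        raise ValueError(f"at most {C.N_NEURONS} outputs per pass; use mac_tiled")
    payloads = _encode_payloads(np.asarray(x, dtype=float))

    # Row pairing: signed input i drives an excitatory row (2i) holding the
    # positive parts of column i of W and an inhibitory row (2i+1) holding
    # the magnitudes of the negative parts.  Output neuron j lives in
    # quadrant j // 128, column j % 128.
    w_exc = np.where(W > 0, W, 0)    # (m, n)
    w_inh = np.where(W < 0, -W, 0)

    array = SynapseArray()
    tau_int = 2e-6
    gamma_current = cfg.gamma_charge / tau_int
    v = np.zeros(m)
    for q0 in range(0, m, C.COLS_PER_QUADRANT):
        q = q0 // C.COLS_PER_QUADRANT
        q1 = min(q0 + C.COLS_PER_QUADRANT, m)
        state = SynapticState(
            n_neurons=C.COLS_PER_QUADRANT,
            tau_syn_exc=tau_int, tau_syn_inh=tau_int, gamma=gamma_current,
        )
        for i in range(n):
            label = i % (C.ADDRESS_MAX + 1)
            array.set_row(q, 2 * i, w_exc[q0:q1, i], np.full(q1 - q0, label), sign=+1)
            array.set_row(q, 2 * i + 1, w_inh[q0:q1, i], np.full(q1 - q0, label), sign=-1)
        for i in range(n):
            label = i % (C.ADDRESS_MAX + 1)
            for row in (2 * i, 2 * i + 1):
                deliver_event(
                    array, state,
                    EventPacket(time=0.0, row=row, label=label,
                                payload=int(payloads[i]), quadrant=q),
                )
        # integrator neurons (all enables off) collect the full charge of
        # each exponential current pulse: Q = I_0 * tau_int
        v[q0:q1] = state.total[: q1 - q0] * tau_int / cfg.C_m
    if cfg.noise_sigma > 0:
        rng = np.random.default_rng(cfg.seed)
        v = v + rng.normal(0.0, cfg.noise_sigma, size=v.shape)
    if quantize:
        half = cfg.dynamic_range
        v = np.clip(v, -half, half)
        v = np.round(v / cfg.lsb) * cfg.lsb
    return v


def mac_tiled(
    weights: np.ndarray,
    x: np.ndarray,
    quantize: bool = True,
    config: MACConfig | None = None,
) -> np.ndarray:
    """Matrix product of arbitrary shape via crossbar-sized tiles.

    ``W`` is split into blocks of at most 128 signed input rows by 512
    output columns; each block runs :func:`mac_forward` and the partial
    results are accumulated digitally at full precision.
    """
    cfg = config or MACConfig()
    W = np.asarray(weights, dtype=np.int64)
    if W.ndim == 1:
        W = W[None, :]
    m, n = W.shape
    x = np.asarray(x, dtype=float)
    out = np.zeros(m)
    for r0 in range(0, m, C.N_NEURONS):
        r1 = min(r0 + C.N_NEURONS, m)
        for c0 in range(0, n, C.COLS_PER_QUADRANT):
            c1 = min(c0 + C.COLS_PER_QUADRANT, n)
            out[r0:r1] += mac_forward(
                W[r0:r1, c0:c1], x[c0:c1], quantize=quantize, config=cfg
            )
    return out
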