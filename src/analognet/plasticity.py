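"""Hybrid-plasticity engine: correlation sensors, quantized row-parallel
readout, and a programmable rule scheduler.

Each synapse carries an analog correlation sensor accumulating
exponentially weighted pre/post spike pairings (the STDP observable):
a postsynaptic spike at ``t_post`` adds ``eta * exp(-(t_post - t_pre)/tau_plus)``
for the nearest preceding presynaptic spike to the causal accumulator, and
symmetrically for the anti-causal one with ``tau_minus``.  Accumulation is
event-driven and exact.

The CADC model digitizes a row of analog values to 8 bits with
saturation, optionally resetting the sensors on read.  Plasticity rules
are synchronous periodic callbacks operating on row-parallel views of the
digital and analog synapse state (weights, addresses, correlation reads,
firing rates), mirroring the embedded processor's row-wise SIMD access;
writes are clipped to the 6-bit weight range and audit-logged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.optimize import curve_fit

from . import constants as C

__all__ = [
    "CorrelationSensorArray",
    "accumulate_pair_correlations",
    "update_correlation",
    "CADCModel",
    "cadc_read",
    "PlasticityRule",
    "RowView",
    "StaticCrossbarContext",
    "run_plasticity_schedule",
    "homeostatic_update",
    "estimate_autocorrelation_time",
]


def accumulate_pair_correlations(
    pre_times,
    post_times,
    eta: float = 1.0,
    tau_plus: float = 10e-6,
    tau_minus: float = 10e-6,
):
    """Exact causal/anti-causal pair accumulation for one synapse.

    Nearest-preceding-spike pairing: each post spike pairs with the latest
    pre spike before it (causal), each pre spike with the latest post spike
    before it (anti-causal).
    """
    pre = np.asarray(sorted(pre_times), dtype=float)
    post = np.asarray(sorted(post_times), dtype=float)
    c_causal = 0.0
    c_acausal = 0.0
    for tp in post:
        k = np.searchsorted(pre, tp, side="right") - 1
        if k >= 0:
            c_causal += eta * np.exp(-(tp - pre[k]) / tau_plus)
    for tq in pre:
        k = np.searchsorted(post, tq, side="right") - 1
        if k >= 0:
            c_acausal += eta * np.exp(-(tq - post[k]) / tau_minus)
    return c_causal, c_acausal


class CorrelationSensorArray:
    """Per-synapse causal/anti-causal correlation accumulators."""

    def __init__(
        self,
        shape: tuple[int, ...],
        eta: float = 1.0,
        tau_plus: float = 10e-6,
        tau_minus: float = 10e-6,
        reset_on_read: bool = True,
    ):
        self.shape = shape
        self.eta = eta
        self.tau_plus = tau_plus
        self.tau_minus = tau_minus
        self.reset_on_read = reset_on_read
        self.c_causal = np.zeros(shape)
        self.c_acausal = np.zeros(shape)

    def process(self, index, pre_times, post_times) -> None:
        """Accumulate pairings of one synapse's pre/post spike trains."""
        cc, ca = accumulate_pair_correlations(
            pre_times, post_times, self.eta, self.tau_plus, self.tau_minus
        )
        self.c_causal[index] += cc
        self.c_acausal[index] += ca

    def reset(self, index=slice(None)) -> None:
        self.c_causal[index] = 0.0
        self.c_acausal[index] = 0.0


def update_correlation(
    sensors: CorrelationSensorArray, index, pre_times, post_times
) -> CorrelationSensorArray:
    """Event-driven sensor update (exact exponential pair weighting)."""
    t = list(pre_times) + list(post_times)
    if any(np.diff(sorted(t)) < 0):
        raise ValueError("event times must be non-decreasing")
    sensors.process(index, pre_times, post_times)
    return sensors


@dataclass
class CADCModel:
    """8-bit columnar ADC: linear map of an analog range to [0, 255]."""

    bits: int = C.CADC_BITS
    sampling_period: float = C.CADC_SAMPLING_PERIOD
    channels: int = C.CADC_CHANNELS_PER_QUADRANT
    v_min: float = 0.0
    v_max: float = 1.0

    @property
    def levels(self) -> int:
        return 2**self.bits

    @property
    def step(self) -> float:
        return (self.v_max - self.v_min) / (self.levels - 1)

    def quantize(self, values: np.ndarray) -> np.ndarray:
        v = np.clip(np.asarray(values, dtype=float), self.v_min, self.v_max)
        return np.round((v - self.v_min) / self.step).astype(int)

    def dequantize(self, codes: np.ndarray) -> np.ndarray:
        return self.v_min + np.asarray(codes) * self.step


def cadc_read(
    values: np.ndarray,
    cadc: CADCModel | None = None,
    sensors: CorrelationSensorArray | None = None,
    index=None,
    reset: bool = False,
) -> np.ndarray:
    """Row-parallel quantized read of analog values (saturating, 8 bit).

    When ``sensors``/``index`` are given the values are read from the
    correlation sensor row and the accumulators are zeroed after the read
    if ``reset``.
    """
    cadc = cadc or CADCModel()
    if sensors is not None:
        values = sensors.c_causal[index] if values is None else values
    codes = cadc.quantize(values)
    if reset and sensors is not None:
        sensors.reset(index)
    return codes


@dataclass
class PlasticityRule:
    """Periodic row-parallel weight-update callback.

    ``callback(view: RowView) -> new_weights or None`` is invoked every
    ``period`` seconds on a consistent snapshot; returned weights are
    clipped to [0, 63] and written back before simulation resumes.
    """

    period: float
    callback: Callable[["RowView"], np.ndarray | None]
    name: str = "rule"


@dataclass
class RowView:
    """Snapshot handed to a plasticity rule: one crossbar row at time t."""

    time: float
    row: int
    weights: np.ndarray
    addresses: np.ndarray | None = None
    correlations_causal: np.ndarray | None = None
    correlations_acausal: np.ndarray | None = None
    rates: np.ndarray | None = None
    membranes: np.ndarray | None = None


class StaticCrossbarContext:
    """Minimal schedulable context: a weight matrix with no dynamics.

    Useful to exercise rule scheduling semantics; richer simulations
    implement the same ``advance``/``row_view``/``write_row`` interface.
    """

    def __init__(self, weights: np.ndarray, addresses: np.ndarray | None = None):
        self.weights = np.asarray(weights, dtype=int).copy()
        self.addresses = addresses
        self.time = 0.0

    def advance(self, t1: float) -> None:
        self.time = t1

    def n_rows(self) -> int:
        return self.weights.shape[0]

    def row_view(self, row: int) -> RowView:
        return RowView(
            time=self.time,
            row=row,
            weights=self.weights[row].copy(),
            addresses=None if self.addresses is None else self.addresses[row].copy(),
        )

    def write_row(self, row: int, weights: np.ndarray) -> None:
        self.weights[row] = weights


def run_plasticity_schedule(
    network,
    rule: PlasticityRule,
    duration: float,
    min_step: float = 0.0,
) -> list[tuple[float, int, int, int, int]]:
    """Run a periodic plasticity rule against a simulation context.

    The callback sees a consistent row-parallel snapshot every period;
    returned weights are clipped to the 6-bit range (clip events counted on
    the log) and applied before the simulation resumes.  Returns the audit
    log of weight writes as ``(time, row, col, old, new)`` tuples, from
    which the exact weight trajectory can be replayed.
    """
    if rule.period < min_step:
        raise ValueError("rule period must cover at least one integration step")
    log: list[tuple[float, int, int, int, int]] = []
    t = 0.0
    n_updates = int(np.floor(duration / rule.period + 1e-9))
    for k in range(1, n_updates + 1):
        t = k * rule.period
        network.advance(t)
        for row in range(network.n_rows()):
            view = network.row_view(row)
            new_w = rule.callback(view)
            if new_w is None:
                continue
            new_w = np.clip(np.asarray(new_w, dtype=int), 0, C.WEIGHT_MAX)
            old = view.weights
            changed = np.nonzero(new_w != old)[0]
            for col in changed:
                log.append((t, row, int(col), int(old[col]), int(new_w[col])))
            network.write_row(row, new_w)
    return log


def homeostatic_update(
    rates: np.ndarray,
    nu_target: float,
    lambda_h: int = 1,
    delta_max: int = 2,
) -> np.ndarray:
    """Integer proportional homeostatic weight step toward a target rate.

    ``dw_i = clip(round(lambda_h (nu_target - nu_i)/nu_target), +-delta_max)``
    applied to the external input weights of neuron i.
    """
    rates = np.asarray(rates, dtype=float)
    dw = np.round(lambda_h * (nu_target - rates) / nu_target)
    return np.clip(dw, -delta_max, delta_max).astype(int)


def estimate_autocorrelation_time(
    series: np.ndarray,
    bin_width: float,
    max_lag: int | None = None,
):
    """Exponential-fit autocorrelation time of a binned activity series.

    Fits ``A exp(-lag/tau)`` to the empirical autocorrelation function and
    returns ``(tau_ac seconds, diagnostics)``.  A non-decaying ACF is
    reported with ``diagnostics["reliable"] = False``.
    """
    x = np.asarray(series, dtype=float)
    x = x - x.mean()
    n = x.size
    var = float(x @ x) / n
    diag = {"reliable": True, "acf1": None}
    if var == 0 or n < 10:
        return float("nan"), {"reliable": False, "acf1": None}
    if max_lag is None:
        max_lag = min(n // 10, 400)
    # FFT-based ACF
    m = int(2 ** np.ceil(np.log2(2 * n)))
    F = np.fft.rfft(x, m)
    acf = np.fft.irfft(F * np.conj(F))[: max_lag + 1]
    acf /= acf[0]
    diag["acf1"] = float(acf[1])

    if acf[1] <= 0:
        # memoryless at the bin resolution
        return 0.5 * bin_width, diag
    if acf[1] >= 0.999:
        diag["reliable"] = False
        return float("inf"), diag

    # fit over lags while the ACF stays clearly positive
    pos = np.nonzero(acf[1:] < 0.03)[0]
    L = int(pos[0]) + 1 if pos.size else max_lag
    L = max(L, 3)
    lags = np.arange(L + 1, dtype=float)
    try:
        tau0 = -1.0 / np.log(acf[1])
        popt, _ = curve_fit(
            lambda k, A, tau: A * np.exp(-k / tau),
            lags,
            acf[: L + 1],
            p0=(1.0, max(tau0, 0.5)),
            maxfev=5000,
        )
        tau_bins = abs(popt[1])
    except RuntimeError:
        tau_bins = -1.0 / np.log(acf[1])
        diag["reliable"] = False
    if not np.all(np.isfinite(acf[: L + 1])):
        diag["reliable"] = False
    diag["fit_lags"] = L
    return float(tau_bins * bin_width), diag
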