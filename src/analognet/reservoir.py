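"""Recurrent spiking reservoirs: collective dynamics under homeostasis.

A small recurrent LIF network (80% excitatory / 20% inhibitory, fixed
recurrent weights, strong enough to be nearly self-sustaining) receives
external Poisson input through ``K_ext`` plastic connections per neuron.
An integer homeostatic rule regulates the 6-bit input weights toward a
target firing rate.  The number of input connections ``K_ext`` is the
control knob of the collective dynamics: with few (strong) inputs the
activity is dominated by recurrent amplification and develops long
autocorrelation times (near-critical regime); many weak inputs drive the
neurons externally and shorten the intrinsic time scale.

The emergent time scales are probed with the autocorrelation time of the
binned population rate, and exploited for reservoir computing: a ridge
readout on low-pass-filtered spike counts is trained on n-bit sum and
parity tasks of the binary input history.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import RidgeClassifier

from .constants import WEIGHT_MAX
from .plasticity import estimate_autocorrelation_time, homeostatic_update

__all__ = ["ReservoirExperiment", "ReservoirNetwork", "run_reservoir_task",
           "measure_tau_ac"]


@dataclass
class ReservoirExperiment:
    """Configuration of a criticality/reservoir experiment."""

    N: int = 32
    n_inputs: int = 32
    K_ext: int = 8
    nu_target: float = 30e3       # Hz, hardware time domain
    task: str = "n_bit_parity"
    n: int = 1                    # memory depth of the task
    seed: int = 0

    def __post_init__(self) -> None:
        if not (1 <= self.K_ext <= self.n_inputs):
            raise ValueError("require 1 <= K_ext <= number of input sources")
        if self.N < 1:
            raise ValueError("N must be >= 1")
        if self.task not in ("n_bit_parity", "n_bit_sum"):
            raise ValueError("unknown task")


class ReservoirNetwork:
    """Discrete-time LIF reservoir with plastic 6-bit input weights.

    Unitless membrane (threshold 1, reset 0), exponential synaptic
    currents, one-step spike propagation delay.  Recurrent weights are
    fixed at construction; external input weights are integers in
    [0, 63] scaled by ``w_unit`` and are subject to homeostasis.
    """

    def __init__(
        self,
        exp: ReservoirExperiment,
        tau_m: float = 20e-6,
        tau_s: float = 5e-6,
        dt: float = 0.5e-6,
        frac_exc: float = 0.8,
        p_rec: float = 0.5,
        j_exc: float = 0.55,
        g_inh: float = 5.0,
        w_unit: float = 0.02,
        t_ref: float = 2e-6,
        homeo_period: float = 100e-6,
        lambda_h: int = 1,
    ):
        self.exp = exp
        self.dt = dt
        self.alpha_m = float(np.exp(-dt / tau_m))
        self.alpha_s = float(np.exp(-dt / tau_s))
        self.kick = (1 - self.alpha_m) * tau_m / tau_s  # V charge per unit I
        self.w_unit = w_unit
        self.homeo_period = homeo_period
        self.lambda_h = lambda_h
        self.ref_steps = max(1, int(round(t_ref / dt)))

        rng = np.random.default_rng(exp.seed)
        N = exp.N
        n_exc = int(round(frac_exc * N))
        sign = np.ones(N)
        sign[n_exc:] = -g_inh
        conn = rng.random((N, N)) < p_rec
        np.fill_diagonal(conn, False)
        self.W_rec = conn * j_exc * sign[None, :]

        # K_ext distinct input sources per neuron
        self.in_mask = np.zeros((N, exp.n_inputs), dtype=bool)
        for i in range(N):
            srcs = rng.choice(exp.n_inputs, size=exp.K_ext, replace=False)
            self.in_mask[i, srcs] = True
        self.w_in = np.where(self.in_mask, 16, 0).astype(int)

        self.rng = rng
        self.reset_state()

    def reset_state(self) -> None:
        N = self.exp.N
        self.V = self.rng.random(N) * 0.5
        self.I = np.zeros(N)
        self.refr = np.zeros(N, dtype=int)
        self.prev_spikes = np.zeros(N, dtype=bool)

    def step(self, input_spikes: np.ndarray) -> np.ndarray:
        """One time step; ``input_spikes`` is a boolean (n_inputs,) vector."""
        drive = (self.w_in * self.w_unit) @ input_spikes.astype(float)
        rec = self.W_rec @ self.prev_spikes.astype(float)
        self.I = self.alpha_s * self.I + drive + rec
        self.V = self.alpha_m * self.V + self.kick * self.I
        self.V[self.refr > 0] = 0.0
        spikes = self.V >= 1.0
        self.V[spikes] = 0.0
        self.refr[spikes] = self.ref_steps
        self.refr[self.refr > 0] -= 1
        self.prev_spikes = spikes
        return spikes

    def run(
        self,
        n_steps: int,
        input_rates,
        homeostasis: bool = True,
        record: bool = False,
    ):
        """Run for ``n_steps``; ``input_rates`` is (n_inputs,) in Hz or a
        callable ``step -> rates``.  Returns the per-step population spike
        count (and the full raster when ``record``)."""
        n_in = self.exp.n_inputs
        pop = np.empty(n_steps, dtype=int)
        raster = np.zeros((n_steps, self.exp.N), dtype=bool) if record else None
        homeo_steps = max(1, int(round(self.homeo_period / self.dt)))
        counts = np.zeros(self.exp.N, dtype=int)
        static = not callable(input_rates)
        if static:
            p_spike = np.asarray(input_rates, dtype=float) * self.dt
        for k in range(n_steps):
            if not static:
                p_spike = np.asarray(input_rates(k), dtype=float) * self.dt
            inp = self.rng.random(n_in) < p_spike
            spikes = self.step(inp)
            counts += spikes
            pop[k] = int(spikes.sum())
            if record:
                raster[k] = spikes
            if homeostasis and (k + 1) % homeo_steps == 0:
                rates = counts / (homeo_steps * self.dt)
                dw = homeostatic_update(
                    rates, self.exp.nu_target, lambda_h=self.lambda_h
                )
                self.w_in = np.clip(
                    self.w_in + dw[:, None] * self.in_mask, 0, WEIGHT_MAX
                )
                counts[:] = 0
        return (pop, raster) if record else (pop, None)


def measure_tau_ac(
    exp: ReservoirExperiment,
    nu_in: float = 50e3,
    warmup: float = 20e-3,
    measure: float = 20e-3,
    bin_width: float = 2e-6,
    network: ReservoirNetwork | None = None,
):
    """Autocorrelation time of the population rate after homeostatic warmup."""
    net = network or ReservoirNetwork(exp)
    rates = np.full(exp.n_inputs, nu_in)
    net.run(int(round(warmup / net.dt)), rates, homeostasis=True)
    pop, _ = net.run(int(round(measure / net.dt)), rates, homeostasis=True)
    bin_steps = max(1, int(round(bin_width / net.dt)))
    n_bins = pop.size // bin_steps
    binned = pop[: n_bins * bin_steps].reshape(n_bins, bin_steps).sum(axis=1)
    tau, diag = estimate_autocorrelation_time(binned, bin_steps * net.dt)
    return tau, diag, net


def run_reservoir_task(
    exp: ReservoirExperiment,
    seed: int | None = None,
    n_bits: int = 500,
    bit_duration: float = 20e-6,
    rate_hi: float = 120e3,
    rate_lo: float = 10e3,
    readout_tau: float = 30e-6,
    alpha: float = 1.0,
    warmup: float = 20e-3,
    network: ReservoirNetwork | None = None,
    train_frac: float = 0.7,
):
    """Train a ridge readout on the reservoir response to a random bit stream.

    Each bit drives all input sources at ``rate_hi`` (bit 1) or ``rate_lo``
    (bit 0) for ``bit_duration``; features are the low-pass-filtered spike
    counts of all neurons sampled at each bit boundary; the target is the
    n-bit parity or sum of the last ``n`` bits.  Homeostatic regulation is
    active throughout.  Returns a dict with train/test accuracy and
    diagnostics (an all-silent reservoir is flagged and scored at chance).
    """
    if seed is not None:
        exp = ReservoirExperiment(**{**exp.__dict__, "seed": seed})
    net = network or ReservoirNetwork(exp)
    rng = np.random.default_rng(exp.seed + 7919)
    bits = rng.integers(0, 2, size=n_bits)

    net.run(int(round(warmup / net.dt)), np.full(exp.n_inputs, 60e3),
            homeostasis=True)

    steps_per_bit = int(round(bit_duration / net.dt))
    alpha_r = float(np.exp(-net.dt / readout_tau))
    filt = np.zeros(exp.N)
    feats = np.empty((n_bits, exp.N))
    for k, b in enumerate(bits):
        rate = rate_hi if b else rate_lo
        p = np.full(exp.n_inputs, rate * net.dt)
        homeo_steps = max(1, int(round(net.homeo_period / net.dt)))
        for s in range(steps_per_bit):
            inp = net.rng.random(exp.n_inputs) < p
            spk = net.step(inp)
            filt = alpha_r * filt + spk
        feats[k] = filt

    if feats.max() == 0:
        return {"flagged_silent": True, "train_accuracy": 0.5,
                "test_accuracy": 0.5, "n": exp.n, "K_ext": exp.K_ext}

    n = exp.n
    valid = np.arange(n - 1, n_bits)
    hist = np.stack([bits[valid - j] for j in range(n)], axis=1)
    if exp.task == "n_bit_parity":
        y = hist.sum(axis=1) % 2
    else:
        y = (hist.sum(axis=1) > n / 2).astype(int)
    X = feats[valid]
    n_train = int(train_frac * len(valid))
    clf = RidgeClassifier(alpha=alpha)
    clf.fit(X[:n_train], y[:n_train])
    return {
        "flagged_silent": False,
        "train_accuracy": float(clf.score(X[:n_train], y[:n_train])),
        "test_accuracy": float(clf.score(X[n_train:], y[n_train:])),
        "n": n,
        "K_ext": exp.K_ext,
        "mean_rate": float(feats.mean()),
    }
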