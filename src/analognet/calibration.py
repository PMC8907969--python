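"""Fixed-pattern noise and measurement-based calibration of analog neurons.

Manufacturing variability gives every analog neuron circuit its own
hidden, static distortion of the nominal model parameters (fixed-pattern
noise, modelled as independent multiplicative log-normal factors).
Calibration never sees these factors: it only runs minimal measurement
protocols on the simulated circuit (a leak-decay fit for tau_m, a slow
current ramp for the threshold, a spike-rate count, ...) and iteratively
adjusts the 10-bit bias codes — one code per controllable parameter,
acting through a monotone saturating transfer curve — until each measured
observable matches its target.

After calibrating a cohort, the "uncalibrated common setting" for
before/after comparisons is the median of the calibrated codes, mirroring
how a shared configuration is chosen for an uncalibrated chip.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .constants import DAC_CODE_MAX, N_ANALOG_PARAMETERS, DEFAULT_DT
from .neuron import (
    AdExParameters,
    SpikeTrain,
    StimulusProtocol,
    simulate_adex_batch,
)

__all__ = [
    "FixedPatternNoiseModel",
    "AnalogInstance",
    "CalibrationTarget",
    "sample_cohort",
    "measure_observable",
    "measure_cohort",
    "calibrate_instance",
    "calibrate_cohort",
    "narrowing_report",
    "OBSERVABLES",
    "regular_bursting_nominal",
    "regular_bursting_targets",
]

# analog parameters subject to fixed-pattern noise; C_m and t_r are set by
# digital configuration and carry no analog mismatch.  Conductance-,
# current- and time-like parameters mismatch multiplicatively (relative
# CV); voltage references mismatch additively (mV-scale offsets).
MULTIPLICATIVE_PARAMS = ("g_l", "Delta_T", "a", "b", "tau_w")
VOLTAGE_PARAMS = ("E_l", "V_T", "V_th", "V_r")
DISTORTED_PARAMS = MULTIPLICATIVE_PARAMS + VOLTAGE_PARAMS

# bias-code assignment: one DAC code per controllable parameter
CODE_MAP = {
    "g_l": 0,
    "E_l": 1,
    "V_th": 2,
    "V_r": 3,
    "b": 4,
    "tau_w": 5,
    "t_r": 6,
    "V_T": 7,
}

# observable id -> (controlled parameter, +1 if observable increases with it)
OBSERVABLES = {
    "tau_m": ("g_l", -1),
    "leak_potential": ("E_l", +1),
    "threshold": ("V_th", +1),
    "reset_potential": ("V_r", +1),
    "adaptation_increment": ("b", +1),
    "tau_w": ("tau_w", +1),
    "refractory": ("t_r", +1),
    "rate_at_I": ("g_l", -1),
}

TRANSFER_RANGE = 1.8    # multiplier at full code deflection
TRANSFER_GAIN = 2.2     # logistic steepness of the code transfer


def code_transfer(code: np.ndarray) -> np.ndarray:
    """Monotone saturating map from a 10-bit code to a gain multiplier.

    Code 512 is approximately unity gain; the ends of the range saturate
    smoothly toward ``TRANSFER_RANGE**(+-tanh(TRANSFER_GAIN/2))``.
    """
    u = (np.asarray(code, dtype=float) - DAC_CODE_MAX / 2) / DAC_CODE_MAX
    return TRANSFER_RANGE ** np.tanh(TRANSFER_GAIN * u)


@dataclass
class FixedPatternNoiseModel:
    """Static per-circuit parameter mismatch.

    Conductance-, current- and time-like parameters receive independent
    multiplicative log-normal factors of coefficient of variation ``cv``;
    voltage references receive additive Gaussian offsets (``v_sigma``
    volts, the scale of threshold/leak mismatch before calibration).
    Draws are reproducible under the seed given to :func:`sample_cohort`.
    """

    cv: float | dict = 0.10
    v_sigma: float = 10e-3
    additive: dict = field(default_factory=dict)

    def cv_for(self, name: str) -> float:
        if isinstance(self.cv, dict):
            return float(self.cv.get(name, 0.0))
        return float(self.cv)

    def sigma_for(self, name: str) -> float:
        return float(self.additive.get(name, self.v_sigma))


class AnalogInstance:
    """One analog neuron circuit: nominal parameters, hidden distortions,
    and settable 10-bit bias codes.

    The hidden distortion factors are only reachable through measurement
    protocols (:func:`measure_observable`); calibration code must not read
    them.
    """

    def __init__(self, nominal: AdExParameters, distortion: dict, offsets: dict):
        self.nominal = nominal
        self.__distortion = dict(distortion)
        self.__offsets = dict(offsets)
        self.bias_codes = np.full(N_ANALOG_PARAMETERS, DAC_CODE_MAX // 2 + 1, dtype=int)

    def set_code(self, param: str, code: int) -> None:
        code = int(code)
        if not (0 <= code <= DAC_CODE_MAX):
            raise ValueError("bias code outside 10-bit range")
        self.bias_codes[CODE_MAP[param]] = code

    def get_code(self, param: str) -> int:
        return int(self.bias_codes[CODE_MAP[param]])

    def _effective(self) -> AdExParameters:
        """Effective circuit parameters (hidden from calibration code)."""
        kw = {}
        for name in DISTORTED_PARAMS + ("t_r",):
            val = getattr(self.nominal, name)
            if name in self.__distortion:
                val = val * self.__distortion[name]
            val = val + self.__offsets.get(name, 0.0)
            if name in CODE_MAP:
                val = val * code_transfer(self.bias_codes[CODE_MAP[name]])
            kw[name] = val
        # circuit headroom: the exponential onset saturates just below the
        # hard threshold, whatever the mismatch
        if self.nominal.enable_exp and kw["V_T"] > kw["V_th"] - 2e-3:
            kw["V_T"] = kw["V_th"] - 2e-3
        return replace(self.nominal, I_exp_max=None, **kw)


@dataclass
class CalibrationTarget:
    """Target value and tolerance for one measurable observable.

    ``param`` optionally overrides which bias code the search adjusts
    (with ``direction`` = +-1 giving the sign of d(observable)/d(code));
    by default the observable's standard control parameter is used.
    Functional observables like the spike rate can thereby calibrate
    parameters that no minimal protocol isolates (e.g. the soft threshold).
    """

    observable: str
    target: float
    tolerance: float
    protocol_args: dict = field(default_factory=dict)
    param: str | None = None
    direction: int | None = None

    def __post_init__(self) -> None:
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if self.observable not in OBSERVABLES:
            raise ValueError(f"unknown observable {self.observable!r}")

    def control(self) -> tuple[str, int]:
        param, direction = OBSERVABLES[self.observable]
        return (self.param or param, self.direction or direction)


def sample_cohort(
    nominal: AdExParameters,
    noise: FixedPatternNoiseModel,
    n: int,
    seed: int,
) -> list[AnalogInstance]:
    """Draw ``n`` instances with independent per-parameter distortions."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    cohort = []
    for _ in range(n):
        dist = {}
        for name in MULTIPLICATIVE_PARAMS:
            cv = noise.cv_for(name)
            if cv > 0:
                sigma = np.sqrt(np.log(1 + cv**2))
                dist[name] = float(rng.lognormal(-sigma**2 / 2, sigma))
            else:
                dist[name] = 1.0
        offs = {}
        for name in VOLTAGE_PARAMS:
            s = noise.sigma_for(name)
            offs[name] = float(rng.normal(0, s)) if s > 0 else 0.0
        cohort.append(AnalogInstance(nominal, dist, offs))
    return cohort


# ---------------------------------------------------------------------------
# measurement protocols (batched over instances)
# ---------------------------------------------------------------------------


def _fit_decay(t, y, y_inf):
    """Log-linear fit of y(t) = y_inf + A exp(-t/tau); returns tau."""
    d = y - y_inf
    s = np.sign(d[0]) if d[0] != 0 else 1.0
    d = s * d
    m = d > max(1e-12, 0.02 * abs(d[0]))
    if m.sum() < 3:
        return float("nan")
    coef = np.polyfit(t[m], np.log(d[m]), 1)
    return -1.0 / coef[0]


def measure_cohort(
    params_list: list[AdExParameters],
    observable: str,
    dt: float = DEFAULT_DT,
    I_probe: float | None = None,
) -> np.ndarray:
    """Run the minimal measurement protocol for one observable on a batch.

    Protocols mirror minimal hardware experiments: leak-decay fits for the
    time constants, a slow current ramp for the threshold, trace minima
    during the clamp for the reset potential, spike counting for rates.
    Returns one measured value per instance (NaN when unmeasurable).
    """
    n = len(params_list)
    if observable == "leak_potential":
        quiet = [replace(p, enable_threshold=False, enable_exp=False,
                         enable_adapt=False) for p in params_list]
        _, V, _, _ = simulate_adex_batch(quiet, lambda t: np.zeros(n), T=30e-6, dt=dt)
        return V[-V.shape[0] // 3:].mean(axis=0)

    if observable == "tau_m":
        quiet = [replace(p, enable_threshold=False, enable_exp=False,
                         enable_adapt=False) for p in params_list]
        t_ch, t_end = 40e-6, 130e-6
        I_ch = 8e-9

        def I_fn(t):
            return np.full(n, I_ch if t < t_ch else 0.0)

        tg, V, _, _ = simulate_adex_batch(quiet, I_fn, T=t_end, dt=dt)
        k_rel = int(round(t_ch / dt)) + 2
        out = np.empty(n)
        # resting level from the fully relaxed tail; fit only the first
        # two decay constants where the signal dominates the tail error
        V_inf = V[-int(15e-6 / dt):].mean(axis=0)
        for i in range(n):
            seg = slice(k_rel, k_rel + int(20e-6 / dt))
            out[i] = _fit_decay(tg[seg] - tg[k_rel], V[seg, i], V_inf[i])
        return out

    if observable == "threshold":
        cfg = [replace(p, enable_adapt=False) for p in params_list]
        T = 150e-6
        dt_f = min(dt, 2e-8)  # fine step: the pre-reset sample approximates
        I_max = np.array([4.0 * p.g_l * max(p.V_th - p.E_l, 0.05)  # V_th to
                          for p in params_list])                   # < 1 mV

        def I_fn(t):
            return I_max * (t / T)

        # hyperpolarizing pre-pulse: start well below any plausible
        # threshold so the upward crossing is always observed; the highest
        # sample before the first reset approximates V_th
        V0 = np.array([p.E_l - 0.15 for p in params_list])
        _, V, _, spikes = simulate_adex_batch(cfg, I_fn, T=T, dt=dt_f, V0=V0)
        out = np.empty(n)
        for i in range(n):
            if spikes[i]:
                k = int(spikes[i][0] / dt_f) + 1
                out[i] = V[:k, i].max()
            else:
                out[i] = V[:, i].max()
        return out

    if observable == "reset_potential":
        cfg = [replace(p, enable_adapt=False) for p in params_list]
        I = np.array([3.0 * p.g_l * max(p.V_th - p.E_l, 0.05) for p in params_list])
        _, V, _, spikes = simulate_adex_batch(cfg, lambda t: I, T=80e-6, dt=dt)
        out = np.full(n, np.nan)
        for i in range(n):
            if spikes[i]:
                k = int(spikes[i][0] / dt) + 2
                k_end = min(k + max(2, int(params_list[i].t_r / dt) - 2), V.shape[0])
                if k_end > k:
                    out[i] = V[k:k_end, i].min()
        return out

    if observable == "adaptation_increment":
        cfg = [replace(p, enable_exp=False) for p in params_list]
        I = np.array([3.0 * p.g_l * max(p.V_th - p.E_l, 0.05) for p in params_list])

        def I_fn(t):
            return I if t < 15e-6 else np.zeros(n)

        _, V, w, spikes = simulate_adex_batch(cfg, I_fn, T=30e-6, dt=dt)
        out = np.full(n, np.nan)
        for i in range(n):
            if spikes[i]:
                k = int(spikes[i][0] / dt)
                if k + 1 < w.shape[0]:
                    out[i] = w[k + 1, i] - w[k, i]
        return out

    if observable == "tau_w":
        cfg = [replace(p, enable_exp=False) for p in params_list]
        I = np.array([3.0 * p.g_l * max(p.V_th - p.E_l, 0.05) for p in params_list])

        def I_fn(t):
            return I if t < 10e-6 else np.zeros(n)

        T = 200e-6
        tg, V, w, spikes = simulate_adex_batch(cfg, I_fn, T=T, dt=dt)
        out = np.full(n, np.nan)
        for i in range(n):
            if not spikes[i]:
                continue
            # fit the adaptation decay well after the membrane has settled
            k0 = int((spikes[i][-1] + 5 * params_list[i].tau_m) / dt)
            seg = slice(k0, V.shape[0])
            out[i] = _fit_decay(tg[seg] - tg[k0], w[seg, i], 0.0)
        return out

    if observable == "refractory":
        cfg = [replace(p, enable_adapt=False) for p in params_list]
        I = np.array([3.0 * p.g_l * max(p.V_th - p.E_l, 0.05) for p in params_list])
        _, V, _, spikes = simulate_adex_batch(cfg, lambda t: I, T=60e-6, dt=dt)
        out = np.full(n, np.nan)
        for i in range(n):
            if spikes[i]:
                k = int(spikes[i][0] / dt) + 1
                eff_Vr = V[k, i]
                cnt = 0
                while k < V.shape[0] and abs(V[k, i] - eff_Vr) < 1e-9:
                    cnt += 1
                    k += 1
                out[i] = cnt * dt
        return out

    if observable == "rate_at_I":
        I_val = I_probe if I_probe is not None else 10e-9
        T = 200e-6
        _, _, _, spikes = simulate_adex_batch(
            params_list, lambda t: np.full(n, I_val), T=T, dt=dt
        )
        return np.array([len(s) / T for s in spikes])

    raise ValueError(f"unknown observable {observable!r}")


def measure_observable(inst: AnalogInstance, observable: str, **kw) -> float:
    """Measure one observable on one instance (batch of one)."""
    return float(measure_cohort([inst._effective()], observable, **kw)[0])


# ---------------------------------------------------------------------------
# calibration search
# ---------------------------------------------------------------------------


def calibrate_cohort(
    instances: list[AnalogInstance],
    targets: list[CalibrationTarget],
    max_iter: int = 12,
) -> list[dict]:
    """Calibrate every target on every instance by synchronous bisection.

    For each target the controlling bias code is bisected over its 10-bit
    range (the transfer curve is monotone, so 1-D bisection is sound); all
    instances are measured together in one batched simulation per
    iteration.  Returns one report per instance:
    ``{observable: {code, measured, residual, iterations, converged}}``.
    """
    n = len(instances)
    reports: list[dict] = [dict() for _ in range(n)]
    for tgt in targets:
        param, direction = tgt.control()
        lo = np.zeros(n, dtype=int)
        hi = np.full(n, DAC_CODE_MAX, dtype=int)
        best_code = np.array([inst.get_code(param) for inst in instances])
        best_err = np.full(n, np.inf)
        it = 0
        for it in range(1, max_iter + 1):
            mid = (lo + hi) // 2
            for inst, c in zip(instances, mid):
                inst.set_code(param, int(c))
            vals = measure_cohort(
                [inst._effective() for inst in instances],
                tgt.observable,
                **tgt.protocol_args,
            )
            err = np.abs(vals - tgt.target)
            better = err < best_err
            best_err = np.where(better, err, best_err)
            best_code = np.where(better, mid, best_code)
            # observable too low -> move the code in the increasing direction
            too_low = (vals < tgt.target) if direction > 0 else (vals > tgt.target)
            lo = np.where(too_low, mid + 1, lo)
            hi = np.where(too_low, hi, mid - 1)
            if np.all(best_err <= tgt.tolerance) or np.all(lo > hi):
                break
        for i, inst in enumerate(instances):
            inst.set_code(param, int(best_code[i]))
            reports[i][tgt.observable] = {
                "code": int(best_code[i]),
                "residual": float(best_err[i]),
                "iterations": it,
                "converged": bool(best_err[i] <= tgt.tolerance),
            }
    return reports


def calibrate_instance(
    inst: AnalogInstance,
    targets: list[CalibrationTarget],
    max_iter: int = 12,
) -> dict:
    """Per-target 1-D bisection on one instance; see :func:`calibrate_cohort`."""
    return calibrate_cohort([inst], targets, max_iter=max_iter)[0]


# ---------------------------------------------------------------------------
# regular-bursting recipe (step-pattern cohort experiments)
# ---------------------------------------------------------------------------


def narrowing_report(
    instances: list[AnalogInstance],
    targets: list[CalibrationTarget],
) -> dict:
    """Before/after spread of each targeted observable across a cohort.

    "Before" uses the uncalibrated common setting — every instance
    configured to the median of the calibrated codes; "after" uses each
    instance's own calibrated codes.  Returns per-observable
    ``{"iqr_pre", "iqr_post", "ratio", "pre", "post"}``; the calibrated
    codes are restored on exit.
    """
    saved = [inst.bias_codes.copy() for inst in instances]
    median_codes = np.median(np.stack(saved), axis=0).astype(int)
    out = {}
    try:
        post = {}
        for tgt in targets:
            post[tgt.observable] = measure_cohort(
                [inst._effective() for inst in instances],
                tgt.observable,
                **tgt.protocol_args,
            )
        for inst in instances:
            inst.bias_codes = median_codes.copy()
        for tgt in targets:
            pre = measure_cohort(
                [inst._effective() for inst in instances],
                tgt.observable,
                **tgt.protocol_args,
            )
            q1, q3 = np.nanpercentile(pre, [25, 75])
            p1, p3 = np.nanpercentile(post[tgt.observable], [25, 75])
            iqr_pre, iqr_post = q3 - q1, p3 - p1
            out[tgt.observable] = {
                "iqr_pre": float(iqr_pre),
                "iqr_post": float(iqr_post),
                "ratio": float(iqr_post / iqr_pre) if iqr_pre > 0 else float("nan"),
                "pre": pre.tolist(),
                "post": post[tgt.observable].tolist(),
            }
    finally:
        for inst, codes in zip(instances, saved):
            inst.bias_codes = codes
    return out


def regular_bursting_nominal() -> AdExParameters:
    """Nominal regular-bursting parameter set (hardware domain).

    Small subthreshold adaptation, sizeable spike-triggered increments and
    a reset just below the soft threshold give recurring bursts under a
    step current; see the firing-pattern experiment defaults.
    """
    from .patterns import PATTERN_SETS

    return PATTERN_SETS["regular_bursting"][0]


def regular_bursting_targets(
    nominal: AdExParameters, I_probe: float = 3.6e-8
) -> list[CalibrationTarget]:
    """Calibration targets pinning the observables the burst pattern needs.

    The soft threshold (exponential onset) has no isolating minimal
    protocol; it is calibrated last, through the firing rate at the burst
    stimulus current, once every other observable is on target.
    """
    rate_nominal = float(
        measure_cohort([nominal], "rate_at_I", I_probe=I_probe)[0]
    )
    return [
        CalibrationTarget("leak_potential", nominal.E_l, 1e-3),
        CalibrationTarget("tau_m", nominal.tau_m, 0.03 * nominal.tau_m),
        CalibrationTarget("threshold", nominal.V_th, 2e-3),
        CalibrationTarget("reset_potential", nominal.V_r, 1e-3),
        CalibrationTarget("adaptation_increment", nominal.b, 0.03 * nominal.b),
        CalibrationTarget("tau_w", nominal.tau_w, 0.03 * nominal.tau_w),
        CalibrationTarget(
            "rate_at_I",
            rate_nominal,
            1.2e4,  # one spike over the 200 us counting window
            protocol_args={"I_probe": I_probe},
            param="V_T",
            direction=-1,
        ),
    ]
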