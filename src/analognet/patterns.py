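"""Named AdEx firing-pattern parameter sets and the step-current sweep.

The regimes follow the classic taxonomy of step-current responses of the
AdEx model: transient spiking needs large spike-triggered increments ``b``
together with strong subthreshold adaptation ``a``; regular bursting and
the initial burst emerge already for small ``a`` and rely on
spike-triggered adaptation, differing in the choice of the reset ``V_r``
relative to the soft threshold ``V_T``; delayed patterns use an inverted
(``a < 0``) subthreshold adaptation providing slow positive feedback.
The numeric values are package defaults chosen to express each regime in
the hardware time domain.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .neuron import (
    AdExParameters,
    ClassifierThresholds,
    SpikeTrain,
    StimulusProtocol,
    classify_firing_pattern,
    run_neuron,
)

__all__ = ["PATTERN_SETS", "default_protocol", "sweep_patterns"]

_BASE = dict(
    C_m=2e-12,
    g_l=2e-7,          # tau_m = 10 us
    E_l=0.40,
    Delta_T=0.008,
    V_T=0.52,
    V_th=0.56,
    t_r=1e-6,
)


def default_protocol(I_0: float) -> StimulusProtocol:
    """Step stimulus I_0 * Theta(t - 50 us) * Theta(400 us - t)."""
    return StimulusProtocol(I_0=I_0, t_on=50e-6, t_off=400e-6, T=500e-6)


# name -> (AdExParameters, StimulusProtocol)
PATTERN_SETS: dict[str, tuple[AdExParameters, StimulusProtocol]] = {
    "tonic": (
        AdExParameters(**_BASE, V_r=0.44, a=0.0, b=0.0, tau_w=50e-6),
        default_protocol(4.4e-8),
    ),
    "transient": (
        AdExParameters(**_BASE, V_r=0.44, a=2e-7, b=4e-8, tau_w=100e-6),
        default_protocol(4.4e-8),
    ),
    "regular_bursting": (
        AdExParameters(**_BASE, V_r=0.545, a=4e-9, b=8e-9, tau_w=30e-6),
        default_protocol(3.6e-8),
    ),
    "initial_burst": (
        AdExParameters(**_BASE, V_r=0.53, a=4e-9, b=1.2e-8, tau_w=120e-6),
        default_protocol(4.0e-8),
    ),
    "delayed_regular_bursting": (
        AdExParameters(**_BASE, V_r=0.545, a=-1.3e-7, b=8e-9, tau_w=50e-6),
        default_protocol(1.3e-8),
    ),
}


def sweep_patterns(
    dt: float = 1e-7,
    thresholds: ClassifierThresholds | None = None,
) -> dict[str, dict]:
    """Run every named parameter set through the step protocol and classify.

    Returns ``{name: {"label": ..., "n_spikes": ..., "spike_times": [...]}}``;
    deterministic.
    """
    out = {}
    for name, (params, protocol) in PATTERN_SETS.items():
        _, V, w, spikes = run_neuron(params, protocol, dt=dt)
        label = classify_firing_pattern(spikes, protocol, thresholds)
        out[name] = {
            "label": label,
            "n_spikes": len(spikes),
            "spike_times": [float(t) for t in spikes.times],
        }
    return out
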