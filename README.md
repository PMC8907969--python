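# analognet

A desk-scale software twin of an accelerated analog neuromorphic core —
the class of mixed-signal chips that emulate spiking neural networks as
physical dynamics, a thousand times faster than biology, with a crossbar
of plastic 6-bit synapses, analog AdEx neuron circuits, row-parallel 8-bit
readout and an embedded plasticity processor.

It is written for computational neuroscientists and neuromorphic-hardware
researchers who want to develop, test and teach the *algorithms* that such
hardware enables — calibration against fixed-pattern mismatch, hybrid
(measured-analog / computed-digital) plasticity, analog matrix
multiplication, and gradient-based training of spiking networks — without
a chip on the desk.

## What is modelled

* **Neuron dynamics** — the adaptive exponential integrate-and-fire model
  `C_m V̇ = −g_l(V−E_l) + g_l Δ_T e^{(V−V_T)/Δ_T} − w + I`,
  `τ_w ẇ = a(V−E_l) − w`, with hard threshold, reset clamp, refractory
  period and feature switches down to LIF and pure charge-integrator
  modes; biological parameter sets enter through an explicit 1000×
  time-domain conversion.  Step-current protocols reproduce the classic
  firing-pattern taxonomy (tonic, transient, bursting, delayed bursting).
* **Multi-compartment neurons** — circuits joined by axial conductances;
  passive EPSP attenuation/broadening along chains, and plateau-type
  dendritic spikes with spatio-temporal coincidence detection.
* **Synaptic crossbar** — four 256×128 quadrants of 6-bit weights with
  6-bit address matching, graded (5-bit) spike payloads, exact
  exponential synaptic currents, and a non-spiking matrix-multiply mode
  with signed row pairs, tiling and 8-bit readout quantization.
* **Hybrid plasticity** — per-synapse causal/anti-causal correlation
  sensors, an 8-bit row-parallel ADC model, a programmable periodic rule
  engine with audit-logged 6-bit weight writes, integer homeostasis, and
  the collective-dynamics experiments: the autocorrelation time of a
  32-neuron recurrent reservoir is controlled by the input strength
  `K_ext` under continuous homeostatic regulation.
* **Calibration** — hidden per-instance fixed-pattern distortions
  (multiplicative CV on conductances/currents/times, additive mV offsets
  on voltage references), 10-bit bias codes with monotone transfer
  curves, and measurement-driven bisection that narrows the observable
  spread of a cohort and restores target behaviour on every instance.
* **Gradients** — the package's analytical core: spiking networks as
  hybrid dynamical systems (flows + jump conditions + transitions), with
  a reverse-time adjoint pass whose event rule follows from the
  implicit-function-theorem derivative of each event time.  Weight
  gradients accumulate only at events; sparse, partial state observations
  enter as Dirac terms; event-coupled subsystems compose by the chain
  rule; a finite-difference oracle validates every fixture.  A separate
  surrogate-gradient path trains from CADC-sampled, 8-bit-quantized
  membrane traces inserted into a discrete computation graph.

See `docs/methods.md` for the models, defaults and their rationale.

## Worked example

Sweep the named AdEx parameter sets through the step-current protocol and
classify each response from its ISI statistics:

```python
from analognet.patterns import sweep_patterns

for name, r in sweep_patterns().items():
    print(f"{name:<26} {r['label']:<26} {r['n_spikes']:3d} spikes")
```

```
tonic                      tonic                       37 spikes
transient                  transient                    1 spikes
regular_bursting           regular_bursting            32 spikes
initial_burst              initial_burst                6 spikes
delayed_regular_bursting   delayed_regular_bursting    10 spikes
```

Each configured regime is recovered by the classifier: the transient set
fires a single onset spike and adapts silent; the regular-bursting set
emits 6–8-spike bursts (≈2 µs intra-burst ISIs) separated by ≈50 µs
adaptation pauses for the whole stimulus; the delayed set stays silent for
~120 µs of positive-feedback build-up before bursting.

Verify the event-based adjoint gradients against central finite
differences on the built-in fixture family (1–5 LIF neurons, feedforward
and recurrent, 0–12 threshold events):

```
$ analognet gradcheck-table
fixture              events  params  max_rel_err  status
1n_subthreshold           0       6     3.48e-08  pass
1n_tonic                  6       6     7.60e-11  pass
3n_chain                  7      14     2.23e-16  pass
2n_recurrent              6       9     1.29e-05  pass
5n_recurrent_inputs      12      40     3.57e-09  pass
```

`max_rel_err` is the worst coordinate-wise relative disagreement between
the adjoint gradient and the finite-difference oracle over all parameters
(time constants, leak, input current, every synaptic weight).

The same experiments are scriptable:
`analognet <firing-patterns|chain|coincidence|criticality|mac|calibrate-cohort|train-surrogate|gradcheck> --config FILE --seed N --out DIR`
writes a `results.json` with full provenance (config hash, seed).

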