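# Methods

`analognet` is a desk-scale software twin of an accelerated analog
neuromorphic core: a crossbar of plastic, address-matched synapses feeding
analog AdEx neuron circuits, digitized by a row-parallel 8-bit ADC and
steered by an embedded plasticity processor.  The package models the
*computational* behaviour of such a core — dynamics, quantization,
fixed-pattern mismatch, calibration, learning — not its transistor-level
electronics.  This note records the models, the numerical choices, the
parameters that matter, and what the synthetic experiments do and do not
show.

## Time domains and units

All internal quantities are SI, in the accelerated "hardware" time domain:
membrane time constants of order 10 µs, voltages of order 0.1–1 V,
conductances of order 10⁻⁷ S.  Biological parameter sets enter only through
`convert_biological_params`, which divides the time constants by the
acceleration factor (default 1000) by scaling the conductances and currents
up while keeping the capacitance and all voltages fixed; the voltage
trajectory is then invariant under the time rescaling.

## Neuron model

The membrane follows the adaptive exponential integrate-and-fire equations

    C_m dV/dt = −g_l (V − E_l) + g_l Δ_T exp((V − V_T)/Δ_T) − w + I
    τ_w dw/dt = a (V − E_l) − w

with a hard firing threshold `V_th`: on crossing, the membrane is clamped to
the reset `V_r` for the refractory time `t_r` and `w` is incremented by `b`.
Feature flags disconnect the exponential and adaptation terms (LIF), the
leak and the threshold (pure charge integrator — the matrix-multiply
operating mode).  Choices the model equations do not determine:

* **Integration** — exponential Euler on the leak term (exact for the
  linear part), explicit exponential/adaptation terms, default step
  `dt = 0.1 µs`.  Threshold crossings are located by linear interpolation
  inside the step (local error O(dt²)).
* **Exponential clamp** — the spike-initiation current saturates at
  `I_exp_max = 50 g_l Δ_T`, mimicking finite circuit currents.
* **`V_th` vs `V_T`** — the hardware distinguishes the soft (exponential
  onset) and hard (comparator) thresholds but no fixed relation exists;
  the default is `V_th = V_T + 5 Δ_T` when not given.
* **Refractoriness** — the membrane is clamped at `V_r`, not frozen; `w`
  keeps evolving.

## Firing-pattern parameter sets

The named step-current response patterns are regimes, not fixed numbers;
the package defaults (hardware domain, τ_m = 10 µs, E_l = 0.40 V,
V_T = 0.52 V, V_th = 0.56 V) were chosen to express each regime clearly:

| pattern | a (S) | b (A) | τ_w (µs) | V_r (V) | I₀ (A) |
|---|---|---|---|---|---|
| tonic | 0 | 0 | 50 | 0.44 | 4.4e−8 |
| transient | 2e−7 | 4e−8 | 100 | 0.44 | 4.4e−8 |
| regular bursting | 4e−9 | 8e−9 | 30 | 0.545 | 3.6e−8 |
| initial burst | 4e−9 | 1.2e−8 | 120 | 0.53 | 4.0e−8 |
| delayed regular bursting | −1.3e−7 | 8e−9 | 50 | 0.545 | 1.3e−8 |

Transient spiking needs large `b` plus strong positive `a` (the adapted
steady state sits below threshold); bursting relies on a reset close to the
soft threshold so the exponential current re-ignites immediately, with the
accumulated `w` terminating each burst; the delayed patterns use inverted
subthreshold adaptation (`a < 0`) as slow positive feedback.  The stimulus
is the step `I₀·Θ(t − 50 µs)·Θ(400 µs − t)` over a 500 µs window.

The pattern classifier is deterministic ISI arithmetic with configurable
thresholds: responses confined to the leading 20 % of the stimulus window
are `transient`; a bimodal ISI split (intra-burst ISI < 0.25 × inter-burst
ISI) recurring until stimulus offset is `regular_bursting`, with a single
leading burst followed by regular ISIs labelled `initial_burst`; a
first-spike latency above 30 % of the window adds the `delayed_` prefix;
near-constant ISIs sustained to offset are `tonic`.  These decision rules
(and their 20 % / 30 % / 0.25 defaults) are package conventions.

## Multi-compartment graphs

Compartments are AdEx/LIF units joined by axial conductances `g_ic`; each
integrates its own equation plus `Σ_j g_ic (V_j − V_i)`, folded into the
exponential-Euler linear part with neighbour voltages held explicit.  The
scheme is linear in the inputs, so passive graphs obey superposition to
machine precision — the basis of the EPSP attenuation/broadening and
linearity tests.  Synaptic input is current-based: an injection of weight
`w` adds `w · 1 nA · exp(−t/τ_syn)` (τ_syn = 2 µs).

Plateau ("dendritic spike") compartments clamp to `V_th + 20 mV` for 10 µs
on threshold crossing, then resume normal dynamics with no adaptation
increment — a phenomenological stand-in for regenerative plateau events,
chosen because their circuit-level equations are not part of the model.
The default coincidence-detection morphology is a chain 0–1–2–3 with a
side branch 4 at compartment 2; compartment 0 is the initiation zone with
threshold 0.412 V (12 mV above rest).  With equal-weight inputs, proximal
pairs (sites 0,1) drive the zone ~33 mV, distal pairs (3,4) ~5 mV, and the
mixed pair (1,3) ~11–13.5 mV depending on order — distal-before-proximal
aligns the two peaks at the zone (the distal EPSP needs ~7 µs to
propagate), which is what places the threshold between the two orders.

## Crossbar and MAC mode

Synapses hold 6-bit weights and 6-bit source addresses; an event carries a
row, a 6-bit label and a 5-bit graded payload (31 = full pulse).  Delivery
increments the excitatory or inhibitory current (per the row driver's
sign) of every matching column by `γ · weight · payload/31`; currents decay
analytically with independent excitatory/inhibitory time constants, so the
event-driven current equals the closed-form kernel sum exactly.  The 5-bit
payload resolution and the linear payload→charge map are package choices
(the hardware encodes activations as pulse lengths; the exact
discretization is not modelled).

In MAC mode the neurons integrate charge (all dynamics flags off).  A
signed input consumes an excitatory/inhibitory row pair holding the
positive and negative parts of one weight column; inputs are encoded as
payloads `round(x·31)`, so even the "unquantized" product carries the 5-bit
encoding error (the r ≥ 0.999 fidelity check measures exactly this).
Readout quantizes the membrane deflection to 8 bits over a configured
dynamic range (±0.6 V default); `γ` is set so a full-weight, full-payload
event deflects an integrator by 1/64 of that range, keeping 64-term sums in
range.  Larger problems are tiled into ≤128-input × ≤512-output blocks and
accumulated digitally at full precision.

## Hybrid plasticity

Each synapse carries causal/anti-causal correlation accumulators updated
event-wise: a post spike adds `η·exp(−Δt/τ₊)` for the nearest preceding pre
spike, and symmetrically for anti-causal pairings with τ₋.
Nearest-preceding (not all-to-all) pairing is a design choice matching
accumulate-per-event sensor semantics.  The CADC model digitizes a row of
analog values to 8 bits with saturation, optionally zeroing the
accumulators on read.

The embedded plasticity processor is abstracted as synchronous periodic
callbacks over row-parallel snapshots (weights, addresses, correlation
reads, rates); instruction-level timing is out of scope.  Writes are
clipped to the 6-bit range and audit-logged as `(time, row, col, old,
new)`; replaying the log reconstructs the weight trajectory exactly.

Homeostasis is integer proportional control on the external input weights:
`Δw = clip(round(λ_h (ν_target − ν)/ν_target), ±2)` per update period.

## Collective dynamics and reservoir computing

The criticality experiments use a 32-neuron recurrent LIF network
(unitless membrane, threshold 1, τ_m = 20 µs, τ_s = 5 µs, dt = 0.5 µs,
2 µs refractory period, one-step spike propagation delay): 80 % excitatory
/ 20 % inhibitory neurons, connection probability 0.5, excitatory weight
0.55 and inhibition 5× stronger — strong enough that recurrence is nearly
self-sustaining.  Each neuron receives `K_ext` of 32 shared Poisson input
sources through plastic 6-bit weights under continuous homeostasis
(period 100 µs, target rate 30 kHz hardware ≈ 30 Hz biological).  All of
these constants are package choices: the network scale is the prototype
scale, and the weight scale was selected during design so that the
low-`K_ext` regime is recurrence-dominated.

With the firing rate pinned by homeostasis, `K_ext` controls the *source*
of the drive: few strong inputs leave the network fluctuation-driven and
near-critical (long autocorrelation time of the binned population rate,
median ~50 µs at K_ext = 4), many weak inputs externalize the drive and
shorten the intrinsic time scale (~10 µs at K_ext = 32).  τ_ac is
estimated by an exponential fit to the empirical ACF of the 2 µs-binned
population rate (FFT-based, fit over the clearly positive lags);
non-decaying ACFs are flagged unreliable.

For the reservoir tasks a random bit stream drives the input sources
(20 µs per bit, 120/10 kHz for 1/0); features are exponentially filtered
spike counts (τ = 30 µs) sampled at each bit boundary, and a ridge readout
(α = 1) is trained on the n-bit parity or sum of the trailing bits.  The
1-bit task reproduces the expected direction — simple tasks profit from
short intrinsic time scales, accuracy increasing with `K_ext` (optimal at
the top of the grid).  **Known limitation:** the complementary effect —
memory-intensive tasks (n ≥ 3) profiting from *low* `K_ext` — does not
resolve at this scale: 5-bit parity stays near chance for every `K_ext`
with 32 neurons and a linear readout, so the task-optimum comparison is
informative only through the n = 1 side.  Passing tests therefore show the
time-scale control and the simple-task direction, not the full task/regime
matching observed on hardware-scale experiments.

## Fixed-pattern noise and calibration

Each analog instance carries hidden static distortions of its nominal
parameters: independent multiplicative log-normal factors (CV 0.10 by
default) on conductance-, current- and time-like parameters
(`g_l, Δ_T, a, b, τ_w`) and additive Gaussian offsets (σ = 10 mV) on the
voltage references (`E_l, V_T, V_th, V_r`).  Additive voltage mismatch is
the physically sensible model — relative noise on an absolute voltage
level would make the mismatch depend on the arbitrary zero of the voltage
scale (and break the `V_th > V_T` ordering for a third of the cohort).
The capacitance and refractory time are digitally configured and carry no
mismatch.  A headroom rule keeps the exponential onset at least 2 mV below
the hard threshold whatever the mismatch.

Calibration sees only measurements, never the distortion factors (they are
name-mangled private state; a test enforces the barrier).  Each
controllable parameter maps to one 10-bit bias code acting through a
monotone logistic-saturating gain `1.8^tanh(2.2·(code−512)/1023)`
(≈ ×0.63…×1.59, unity at mid-scale), wide enough to cancel ±3σ mismatch.
Measurement protocols are minimal experiments on the simulated circuit:

* `leak_potential` — resting membrane average;
* `tau_m` — exponential fit to the decay after a subthreshold charge pulse;
* `threshold` — slow current ramp from a hyperpolarized start; the highest
  sample before the first reset (fine 20 ns step keeps the bias < 1 mV);
* `reset_potential` — trace minimum during the post-spike clamp;
* `adaptation_increment` — jump of the recorded adaptation state at a spike;
* `tau_w` — exponential fit to the adaptation decay after the membrane has
  re-settled;
* `refractory` — duration of the clamp at the reset potential;
* `rate_at_I` — spike count at a probe current over 200 µs.

Calibration is synchronous integer bisection of the controlling code
(sound because the transfer is monotone), batched across the cohort, with
the best-measured code kept; 12 measurements per target suffice for the
10-bit range.  The regular-bursting recipe calibrates `E_l`, τ_m, `V_th`,
`V_r`, `b`, τ_w and finally the soft threshold `V_T` — which no minimal
protocol isolates — through the firing rate at the burst stimulus current
(a functional observable, calibrated last so the other parameters are
already on target).  `reset_potential` and `adaptation_increment` extend
the basic observable list because the burst pattern is first-order
sensitive to `V_r` and `b`; both are directly readable from the recorded
traces.  The remaining mismatched parameters (`a`, `Δ_T`) stay
uncalibrated; the bursting pattern is second-order sensitive to them.

Before/after comparisons configure every instance to the median of the
calibrated codes ("uncalibrated common setting") and compare interquartile
ranges per observable; at CV 0.10 the post/pre IQR ratios are 0.03–0.17,
and all 128 instances of a cohort classify as regular bursting after
calibration.

## Event-based adjoint gradients

Spiking networks are treated as hybrid dynamical systems: smooth flows
`dx/dt = f(x, p, t)` with jumps `x⁺ = T_r(x⁻)` when a condition
`j_r(x, p, t)` crosses zero.  The reference instance is the current-based
LIF network (state `(V, I)` per neuron, threshold `V_i = V_T`, reset plus
`I⁺ = I⁻ + W e_i`), with the flat parameter vector
`[τ_m, τ_s, V_L, R, I_bias] + W + W_in`.

Gradients come from a reverse-time adjoint pass.  Between events
`dλ/dt = −Jᵀλ − (∂l/∂x)ᵀ`; at each event the adjoint propagates through
the total derivative of the post-event state with respect to the pre-event
state at the implicitly defined event time,

    dt*/dx⁻ = −(∂j/∂x) / (∂j/∂x · f⁻ + ∂j/∂t)
    D = ∂T/∂x + (f⁺ − ∂T/∂x f⁻) (−dt*/dx⁻)ᵀ ,   λ⁻ = Dᵀ λ⁺

with an additional `(l⁻ − l⁺)·dt*/dx⁻` term when the loss integrand is
discontinuous across the jump.  Transition parameters (weights) accumulate
gradient only at events (`dL/dW[:, i] += λ⁺_I` at spikes of neuron i — so
weights without a presynaptic spike get exactly zero); flow parameters
accumulate `∫ λᵀ ∂f/∂p dt`, carried as extra quadrature states of the
backward RK4 integration.  Sparse observations `|P x(t_i) − x̂_i|²` add
Dirac terms `2 Pᵀ(P x − x̂)` to λ at the observation times.  Event-coupled
subsystems compose by the chain rule: the downstream pass reports dL/dt of
its input events, which seed the upstream pass at the corresponding output
events.

Numerics: forward and backward use the same fixed-step classical RK4
(default 0.05 µs for the gradient fixtures) on the same stored grid;
event times are bisected to ~machine precision inside the step; the
backward pass interpolates the stored states with cubic Hermite
polynomials.  Tangential ("grazing") crossings, where the transversality
denominator falls below 10⁻⁹, are flagged and not smoothed — the gradient
is genuinely undefined there.  Simultaneous events are processed in
ascending condition index.  The independent oracle is a central
finite-difference gradient on the same grid, with per-coordinate steps
scaled to each parameter's magnitude and coordinates whose perturbation
changes the event count flagged non-differentiable; on the fixture family
(1–5 neurons, feedforward and recurrent, 0–12 events) the two agree
coordinate-wise to better than 10⁻⁴.

## Surrogate gradients from sampled traces

The surrogate path models the network as a discrete-time LIF graph at the
CADC sampling period, whose hidden membrane state is *overwritten* each
step by the measured (8-bit quantized) traces, so backpropagation
linearizes around the physically observed dynamics.  The spike
nonlinearity uses the SuperSpike-style surrogate
`σ′(v) = (1 + β|v − v_th|)⁻²` (β = 10 per unit threshold range), the
quantization a straight-through estimator, and the reset is by subtraction
and detached from the gradient.  Readout is a non-spiking leaky
integrator; class scores are max-over-time membrane values under softmax
cross-entropy, optionally with an activity (sparsity) penalty.  When the
inserted traces come from the graph itself the procedure reproduces the
graph's native BPTT gradient exactly (a test asserts bit-equality).
Training uses Adam on a two-class 16×16 latency-encoded synthetic task
(100 samples per class, 40 steps); it reaches 100 % training accuracy
within ten epochs on every seed tested — far inside the 200-epoch budget.

## Synthetic data

Poisson event lists are exact (uniform order statistics given a Poisson
count).  The latency datasets use random smooth blob templates per class,
per-sample Gaussian pixel noise (σ = 0.08), and the encoding
`t = t_max(1 − intensity)` with sub-threshold pixels silent; at
separation ≥ 1 linear separability is verified with a logistic probe at
generation time.  These stand-ins share the latency code and dimensionality
of the hardware benchmarks but none of their intra-class structure, so
trainability results here demonstrate the gradient machinery, not
benchmark-level performance.

## Problem sizes

Defaults are desk-scale by design: gradient fixtures of 1–5 neurons and
60 µs, cohorts of 128 instances, reservoirs of 32 neurons with 20–40 ms
runs, 200-sample training sets.  The full-size crossbar (4 × 256 × 128) and
its constants are modelled exactly; experiments use as many columns as the
problem needs.
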