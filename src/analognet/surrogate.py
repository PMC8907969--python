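"""Surrogate-gradient training from sampled membrane traces.

The continuous network dynamics are modelled by a discrete-time LIF
computation graph with step equal to the CADC sampling period.  Membrane
traces measured on the (simulated) analog substrate — sampled at that
period and quantized to 8 bits — are inserted into the graph at every
time step, overwriting its forward state, so the backward pass linearizes
around the actually observed dynamics ("trace insertion").  The
non-differentiable spike nonlinearity is given a SuperSpike-style
surrogate derivative

    sigma'(v) = 1 / (1 + beta |v - v_th|)^2

and the 8-bit quantization a straight-through estimator.  Gradients are
backpropagated through time by hand (the graph is small and explicit).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import CADC_LEVELS

__all__ = ["SurrogateNetwork", "quantize_trace", "train_latency_task"]


def quantize_trace(v: np.ndarray, v_min: float = -2.0, v_max: float = 2.0) -> np.ndarray:
    """8-bit quantization of a membrane trace over [v_min, v_max]."""
    lsb = (v_max - v_min) / (CADC_LEVELS - 1)
    q = np.round((np.clip(v, v_min, v_max) - v_min) / lsb)
    return v_min + q * lsb


@dataclass
class SurrogateNetwork:
    """Feedforward spiking network: input spikes -> LIF hidden -> LI readout.

    Discrete dynamics per step (decay factors ``alpha = exp(-dt/tau)``)::

        i_h[t] = alpha_s i_h[t-1] + S_in[t] W_in^T
        v_h[t] = alpha_m v_h[t-1] + (1 - alpha_m) i_h[t] - v_th s_h[t-1]
        s_h[t] = H(v_h[t] - v_th)

    The readout layer integrates hidden spikes without spiking; class
    scores are the per-class maxima of the readout membrane over time.
    Reset is by subtraction and detached from the gradient.
    """

    n_in: int
    n_hidden: int
    n_out: int
    alpha_m: float = 0.94
    alpha_s: float = 0.88
    v_th: float = 1.0
    beta: float = 10.0
    seed: int = 0
    W_in: np.ndarray = field(default=None)   # type: ignore[assignment]
    W_out: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        rng = np.random.default_rng(self.seed)
        if self.W_in is None:
            self.W_in = rng.normal(0, 1.5 / np.sqrt(self.n_in),
                                   (self.n_hidden, self.n_in))
        if self.W_out is None:
            self.W_out = rng.normal(0, 1.0 / np.sqrt(self.n_hidden),
                                    (self.n_out, self.n_hidden))

    # -- forward ------------------------------------------------------------
    def forward(self, S_in: np.ndarray):
        """Run the graph on input spikes ``S_in`` of shape (B, T, n_in).

        Returns a dict with hidden currents/membranes/spikes and readout
        membranes, all with a leading (B, T) shape.
        """
        B, T, _ = S_in.shape
        i_h = np.zeros((B, self.n_hidden))
        v_h = np.zeros((B, self.n_hidden))
        s_h = np.zeros((B, self.n_hidden))
        i_o = np.zeros((B, self.n_out))
        v_o = np.zeros((B, self.n_out))
        out = {
            "i_h": np.empty((B, T, self.n_hidden)),
            "v_h": np.empty((B, T, self.n_hidden)),
            "s_h": np.empty((B, T, self.n_hidden)),
            "v_o": np.empty((B, T, self.n_out)),
        }
        for t in range(T):
            i_h = self.alpha_s * i_h + S_in[:, t] @ self.W_in.T
            v_h = self.alpha_m * v_h + (1 - self.alpha_m) * i_h - self.v_th * s_h
            s_h = (v_h >= self.v_th).astype(float)
            i_o = self.alpha_s * i_o + s_h @ self.W_out.T
            v_o = self.alpha_m * v_o + (1 - self.alpha_m) * i_o
            out["i_h"][:, t] = i_h
            out["v_h"][:, t] = v_h
            out["s_h"][:, t] = s_h
            out["v_o"][:, t] = v_o
        return out

    def logits(self, v_o: np.ndarray) -> np.ndarray:
        return v_o.max(axis=1)

    def loss(self, S_in, labels, sparsity: float = 0.0):
        fwd = self.forward(S_in)
        return self._loss_from(fwd, labels, sparsity) + (fwd,)

    def _loss_from(self, fwd, labels, sparsity):
        z = self.logits(fwd["v_o"])
        z = z - z.max(axis=1, keepdims=True)
        p = np.exp(z)
        p /= p.sum(axis=1, keepdims=True)
        B = len(labels)
        ce = -np.mean(np.log(p[np.arange(B), labels] + 1e-12))
        if sparsity:
            ce = ce + sparsity * fwd["s_h"].mean()
        acc = float(np.mean(np.argmax(z, axis=1) == np.asarray(labels)))
        return ce, acc

    def surrogate_deriv(self, v: np.ndarray) -> np.ndarray:
        return 1.0 / (1.0 + self.beta * np.abs(v - self.v_th)) ** 2

    # -- backward -----------------------------------------------------------
    def surrogate_backward(
        self,
        S_in: np.ndarray,
        labels: np.ndarray,
        traces: np.ndarray | None = None,
        spikes: np.ndarray | None = None,
        sparsity: float = 0.0,
    ):
        """BPTT weight gradients, optionally around inserted measured traces.

        ``traces``/``spikes`` of shape (B, T, n_hidden), when given, replace
        the graph's own hidden membrane/spike state at every step (sampled
        at the CADC period, possibly 8-bit quantized; the quantization is
        handled straight-through).  Without insertion this is the graph's
        native BPTT gradient.  Returns ``(grads, loss, accuracy)``.
        """
        B, T, _ = S_in.shape
        fwd = self.forward(S_in)
        v_h = fwd["v_h"] if traces is None else traces
        s_h = fwd["s_h"] if spikes is None else spikes
        if traces is not None and traces.shape != fwd["v_h"].shape:
            raise ValueError("trace/spike arrays misaligned with the graph grid")

        # recompute readout from the (possibly inserted) hidden spikes
        i_o = np.zeros((B, self.n_out))
        v_o = np.empty((B, T, self.n_out))
        prev = np.zeros((B, self.n_out))
        for t in range(T):
            i_o = self.alpha_s * i_o + s_h[:, t] @ self.W_out.T
            prev = self.alpha_m * prev + (1 - self.alpha_m) * i_o
            v_o[:, t] = prev
        fwd_eff = {"v_o": v_o, "s_h": s_h}
        loss, acc = self._loss_from(fwd_eff, labels, sparsity)

        # dL/dlogits
        z = self.logits(v_o)
        zs = z - z.max(axis=1, keepdims=True)
        p = np.exp(zs)
        p /= p.sum(axis=1, keepdims=True)
        dz = p.copy()
        dz[np.arange(B), labels] -= 1.0
        dz /= B

        # max-over-time routes dL/dz to the argmax step
        t_star = v_o.argmax(axis=1)                      # (B, n_out)
        dv_o = np.zeros_like(v_o)
        b_ix = np.arange(B)[:, None]
        o_ix = np.arange(self.n_out)[None, :]
        dv_o[b_ix, t_star, o_ix] = dz

        gW_out = np.zeros_like(self.W_out)
        gW_in = np.zeros_like(self.W_in)
        d_io = np.zeros((B, self.n_out))
        d_vo = np.zeros((B, self.n_out))
        d_sh = np.zeros((B, self.n_hidden))
        d_vh = np.zeros((B, self.n_hidden))
        d_ih = np.zeros((B, self.n_hidden))
        ds_const = sparsity / (B * T * self.n_hidden) if sparsity else 0.0
        for t in range(T - 1, -1, -1):
            d_vo = d_vo + dv_o[:, t]
            d_io = self.alpha_s * d_io + (1 - self.alpha_m) * d_vo
            d_sh_t = d_io @ self.W_out + d_sh + ds_const
            gW_out += d_io.T @ s_h[:, t]
            # spike nonlinearity: surrogate derivative at the (inserted) v
            sg = self.surrogate_deriv(v_h[:, t])
            d_vh = d_vh + d_sh_t * sg
            d_ih = self.alpha_s * d_ih + (1 - self.alpha_m) * d_vh
            gW_in += d_ih.T @ S_in[:, t]
            # carry to t-1 (reset detached)
            d_vh = self.alpha_m * d_vh
            d_vo = self.alpha_m * d_vo
            d_sh = np.zeros_like(d_sh)
        return {"W_in": gW_in, "W_out": gW_out}, loss, acc


def train_latency_task(
    net: SurrogateNetwork,
    S_in: np.ndarray,
    labels: np.ndarray,
    epochs: int = 200,
    lr: float = 0.3,
    sparsity: float = 0.0,
    insert_quantized_traces: bool = True,
    target_accuracy: float | None = None,
):
    """Adam training loop with per-epoch trace sampling and insertion.

    Each epoch runs the forward model, samples its hidden membrane traces
    at the graph step (8-bit quantized when ``insert_quantized_traces``),
    and backpropagates around the inserted traces.  Returns the history of
    (loss, accuracy) per epoch.
    """
    m = {k: np.zeros_like(v) for k, v in (("W_in", net.W_in), ("W_out", net.W_out))}
    v2 = {k: np.zeros_like(val) for k, val in m.items()}
    b1, b2, eps = 0.9, 0.999, 1e-8
    hist = []
    for ep in range(1, epochs + 1):
        if insert_quantized_traces:
            fwd = net.forward(S_in)
            traces = quantize_trace(fwd["v_h"])
            spikes = fwd["s_h"]
        else:
            traces = spikes = None
        grads, loss, acc = net.surrogate_backward(
            S_in, labels, traces=traces, spikes=spikes, sparsity=sparsity
        )
        for k, W in (("W_in", net.W_in), ("W_out", net.W_out)):
            m[k] = b1 * m[k] + (1 - b1) * grads[k]
            v2[k] = b2 * v2[k] + (1 - b2) * grads[k] ** 2
            mh = m[k] / (1 - b1**ep)
            vh = v2[k] / (1 - b2**ep)
            W -= lr * mh / (np.sqrt(vh) + eps)
        hist.append((loss, acc))
        if target_accuracy is not None and acc >= target_accuracy:
            break
    return hist
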