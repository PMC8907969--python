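"""Synthetic input generators: Poisson event trains and latency-coded images.

All test inputs are generated here — independent Poisson processes
standing in for the on-chip event sources, and small 16x16 synthetic
image datasets whose pixels are encoded as single-spike latencies
(bright pixels spike early, dim pixels late, near-black pixels stay
silent).  The class templates are random smooth blobs with per-sample
pixel noise; at separation >= 1 the generator verifies linear
separability with a logistic probe and redraws templates if necessary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.linear_model import LogisticRegression

__all__ = ["generate_poisson_inputs", "SyntheticImage", "generate_latency_dataset",
           "latency_encode", "spike_raster"]


def generate_poisson_inputs(rates, T: float, seed: int) -> np.ndarray:
    """Independent Poisson event lists for each source.

    ``rates`` is a per-source array in Hz (hardware time).  Returns a
    structured (n_events, 2) float array of ``(time_s, source)`` rows
    sorted by time; reproducible under the seed.
    """
    rates = np.asarray(rates, dtype=float)
    if np.any(rates < 0):
        raise ValueError("rates must be non-negative")
    rng = np.random.default_rng(seed)
    rows = []
    for src, r in enumerate(rates):
        if r <= 0:
            continue
        n = rng.poisson(r * T)
        times = np.sort(rng.uniform(0.0, T, size=n))
        rows.append(np.column_stack([times, np.full(n, src, dtype=float)]))
    if not rows:
        return np.empty((0, 2))
    ev = np.concatenate(rows)
    return ev[np.argsort(ev[:, 0], kind="stable")]


@dataclass
class SyntheticImage:
    """16x16 intensity grid in [0, 1] with a class label."""

    pixels: np.ndarray
    label: int


def _blob_template(rng: np.random.Generator, size: int = 16) -> np.ndarray:
    """Random smooth blob: a few Gaussian bumps on a 16x16 grid."""
    yy, xx = np.mgrid[0:size, 0:size]
    img = np.zeros((size, size))
    for _ in range(rng.integers(2, 4)):
        cy, cx = rng.uniform(2, size - 2, 2)
        s = rng.uniform(1.5, 3.5)
        a = rng.uniform(0.6, 1.0)
        img += a * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * s**2))
    return np.clip(img / img.max(), 0, 1)


def generate_latency_dataset(
    n_per_class: int,
    classes: int = 2,
    separation: float = 1.0,
    seed: int = 0,
    noise: float = 0.08,
    max_redraws: int = 20,
) -> list[SyntheticImage]:
    """Latency-codable image dataset with controllable class separation.

    Each sample is ``separation * template + pixel noise`` (clipped to
    [0, 1]); at separation 0 the classes are indistinguishable by
    construction.  For separation >= 1 linear separability (>= 99% with a
    logistic probe on raw pixels) is verified at generation time and the
    templates redrawn if the check fails.
    """
    if classes < 2:
        raise ValueError("need at least two classes")
    rng = np.random.default_rng(seed)
    for _ in range(max_redraws):
        templates = [_blob_template(rng) for _ in range(classes)]
        X, y, images = [], [], []
        for c in range(classes):
            for _ in range(n_per_class):
                px = separation * templates[c] + rng.normal(0, noise, (16, 16))
                px = np.clip(px, 0, 1)
                images.append(SyntheticImage(pixels=px, label=c))
                X.append(px.ravel())
                y.append(c)
        if separation < 1.0:
            return images
        probe = LogisticRegression(max_iter=2000)
        probe.fit(np.asarray(X), np.asarray(y))
        if probe.score(np.asarray(X), np.asarray(y)) >= 0.99:
            return images
    raise RuntimeError("failed to generate a separable dataset")


def latency_encode(
    image: SyntheticImage,
    t_max: float = 50e-6,
    threshold: float = 0.05,
) -> np.ndarray:
    """Per-pixel spike times ``t = t_max (1 - intensity)``.

    Pixels below the intensity threshold stay silent (time = NaN); each
    active pixel emits exactly one spike.
    """
    px = image.pixels.ravel()
    t = t_max * (1.0 - px)
    t[px < threshold] = np.nan
    return t


def spike_raster(
    images: list[SyntheticImage],
    n_steps: int = 40,
    t_max: float = 50e-6,
    threshold: float = 0.05,
) -> np.ndarray:
    """Binary (B, T, 256) spike tensor of latency-encoded images."""
    B = len(images)
    out = np.zeros((B, n_steps, 256))
    dt = t_max / n_steps
    for b, img in enumerate(images):
        t = latency_encode(img, t_max=t_max, threshold=threshold)
        act = ~np.isnan(t)
        steps = np.minimum((t[act] / dt).astype(int), n_steps - 1)
        out[b, steps, np.nonzero(act)[0]] = 1.0
    return out
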