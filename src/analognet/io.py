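"""Reading and writing the package's plain-text interchange formats.

* parameter sets: flat ``key: value`` text (YAML subset) with an explicit
  ``domain: biological|hardware`` tag;
* membrane traces: CSV ``time_s,neuron_id,V,w`` (plus ``compartment_id``
  for multi-compartment recordings);
* spike trains: CSV ``time_s,neuron_id`` sorted by time;
* event lists: CSV ``time_s,row,label,payload``;
* experiment configuration: a single YAML file, schema-checked by the
  experiment drivers.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .neuron import AdExParameters

__all__ = [
    "save_params", "load_params",
    "save_traces", "load_traces",
    "save_spikes", "load_spikes",
    "save_events", "load_events",
    "load_config", "config_hash", "save_results",
]


def save_params(params: AdExParameters, path) -> None:
    d = dataclasses.asdict(params)
    Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def load_params(path) -> AdExParameters:
    d = yaml.safe_load(Path(path).read_text())
    return AdExParameters(**d)


def save_traces(path, t, V, w=None, neuron_ids=None, compartment=False) -> None:
    """Write traces as ``time_s,neuron_id,V,w`` rows (one row per sample)."""
    V = np.atleast_2d(np.asarray(V).T).T  # (T, n)
    n = V.shape[1]
    ids = np.arange(n) if neuron_ids is None else np.asarray(neuron_ids)
    frames = []
    for j in range(n):
        df = pd.DataFrame({
            "time_s": t,
            ("compartment_id" if compartment else "neuron_id"): ids[j],
            "V": V[:, j],
            "w": (np.zeros_like(t) if w is None else np.asarray(w)[:, j]
                  if np.asarray(w).ndim == 2 else np.asarray(w)),
        })
        frames.append(df)
    pd.concat(frames).to_csv(path, index=False)


def load_traces(path) -> pd.DataFrame:
    return pd.read_csv(path)


def save_spikes(path, spikes) -> None:
    """``spikes`` is a list of per-neuron spike-time lists."""
    rows = [(t, i) for i, ts in enumerate(spikes) for t in ts]
    rows.sort()
    pd.DataFrame(rows, columns=["time_s", "neuron_id"]).to_csv(path, index=False)


def load_spikes(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if not df["time_s"].is_monotonic_increasing:
        df = df.sort_values("time_s")
    return df


def save_events(path, events) -> None:
    """``events`` is an iterable of (time_s, row, label, payload)."""
    pd.DataFrame(
        list(events), columns=["time_s", "row", "label", "payload"]
    ).to_csv(path, index=False)


def load_events(path) -> pd.DataFrame:
    return pd.read_csv(path)


def load_config(path) -> dict:
    cfg = yaml.safe_load(Path(path).read_text())
    if not isinstance(cfg, dict):
        raise ValueError("experiment config must be a mapping")
    return cfg


def config_hash(cfg: dict) -> str:
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def save_results(path, results: dict, cfg: dict | None = None) -> None:
    """Write a results JSON with provenance (config hash, seeds)."""
    out = dict(results)
    if cfg is not None:
        out["_provenance"] = {
            "config_hash": config_hash(cfg),
            "seed": cfg.get("seed"),
        }
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(out, indent=2, sort_keys=True, default=float))
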