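"""File interchange: tidy CSV for spikes, LFP and bursts; YAML run configs;
JSON manifests.

All formats round-trip exactly (write -> read -> write produces identical
frames) at the printed precision.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .detect import GammaBurst
from .network import SimResult

__all__ = [
    "write_spikes", "read_spikes", "write_lfp", "read_lfp",
    "write_bursts", "read_bursts", "write_manifest", "load_config",
]


def write_spikes(path, sim_or_times, ids=None) -> None:
    """Spike table as CSV with columns (neuron_id, time_ms)."""
    if isinstance(sim_or_times, SimResult):
        times, ids = sim_or_times.spike_times, sim_or_times.spike_ids
    else:
        times = np.asarray(sim_or_times)
        ids = np.asarray(ids)
    pd.DataFrame({"neuron_id": ids, "time_ms": times}).to_csv(path, index=False)


def read_spikes(path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path)
    return df["time_ms"].to_numpy(float), df["neuron_id"].to_numpy(np.int64)


def write_lfp(path, t_ms, lfp_uv) -> None:
    pd.DataFrame({"time_ms": t_ms, "lfp_uV": lfp_uv}).to_csv(path, index=False)


def read_lfp(path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path)
    return df["time_ms"].to_numpy(float), df["lfp_uV"].to_numpy(float)


def write_bursts(path, bursts) -> None:
    pd.DataFrame([{"electrode_id": b.electrode_id, "start_ms": b.start,
                   "end_ms": b.end} for b in bursts]).to_csv(path, index=False)


def read_bursts(path) -> list[GammaBurst]:
    df = pd.read_csv(path)
    return [GammaBurst(start=r.start_ms, end=r.end_ms,
                       electrode_id=int(r.electrode_id))
            for r in df.itertuples()]


def write_manifest(path, **entries) -> None:
    """JSON manifest of parameters/seeds for a pipeline stage."""
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        return str(o)
    Path(path).write_text(json.dumps(entries, indent=2, default=default,
                                     sort_keys=True))


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def read_current_trace(path) -> tuple[np.ndarray, np.ndarray]:
    """Two-column CSV (time_ms, current_nA) for single-neuron drives."""
    df = pd.read_csv(path)
    return df["time_ms"].to_numpy(float), df["current_nA"].to_numpy(float)


def write_current_trace(path, t_ms, current_na) -> None:
    pd.DataFrame({"time_ms": t_ms, "current_nA": current_na}).to_csv(
        path, index=False)


def network_spec_to_dict(spec) -> dict:
    """Serializable form of a NetworkSpec (cell presets referenced by name)."""
    drive = spec.drive
    return {
        "name": spec.name, "state": spec.state, "scale": spec.scale,
        "tau_e": spec.tau_e, "tau_i": spec.tau_i,
        "populations": [{"name": p.name, "size": p.size}
                        for p in spec.populations],
        "groups": [{"source": g.source, "target": g.target,
                    "p_connect": g.p_connect, "q": g.q, "sign": g.sign,
                    "delay": g.delay} for g in spec.groups],
        "drive": {"rate": drive.rate, "q": drive.q,
                  "n_sources": drive.n_sources, "p_connect": drive.p_connect,
                  "mode": drive.mode, "n_per_neuron": drive.n_per_neuron},
    }


def write_network_spec(path, spec) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(network_spec_to_dict(spec), fh, sort_keys=False)


def read_network_spec(path):
    """Rebuild a NetworkSpec from its YAML form (cell presets by name)."""
    from .cells import cell_params
    from .network import DriveSpec, NetworkSpec, PopulationSpec, SynapseGroup
    with open(path) as fh:
        d = yaml.safe_load(fh)
    pops = tuple(PopulationSpec(p["name"], p["size"], cell_params(p["name"]))
                 for p in d["populations"])
    groups = tuple(SynapseGroup(**g) for g in d["groups"])
    drive = DriveSpec(**d["drive"])
    return NetworkSpec(d["name"], pops, groups, d["tau_e"], d["tau_i"],
                       drive, d.get("state", "gamma"), d.get("scale", 1.0))
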