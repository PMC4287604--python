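"""Spike-train tables, weight trajectories and run manifests.

Spike sets are exchanged as tidy tables with columns
``neuron_id, trial_id, spike_time_ms`` — written either as plain CSV or as
an HDF5 container with the same schema; both round-trip losslessly.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .spiketrains import SpikeTrain

__all__ = [
    "trains_to_frame",
    "frame_to_trains",
    "write_spikes_csv",
    "read_spikes_csv",
    "write_spikes_h5",
    "read_spikes_h5",
    "write_manifest",
]


def trains_to_frame(trains: dict) -> pd.DataFrame:
    rows = []
    for neuron_id, lst in trains.items():
        for tr in lst:
            rows.append(pd.DataFrame({
                "neuron_id": neuron_id,
                "trial_id": tr.trial_id,
                "spike_time_ms": tr.spike_times,
            }))
    if not rows:
        return pd.DataFrame(columns=["neuron_id", "trial_id", "spike_time_ms"])
    return pd.concat(rows, ignore_index=True)


def frame_to_trains(df: pd.DataFrame, duration_ms: float) -> dict:
    trains: dict = {}
    neuron_ids = sorted(df["neuron_id"].unique()) if len(df) else []
    trial_ids = sorted(df["trial_id"].unique()) if len(df) else []
    for nid in neuron_ids:
        trains[int(nid)] = []
        for tid in trial_ids:
            sel = df[(df["neuron_id"] == nid) & (df["trial_id"] == tid)]
            times = np.sort(sel["spike_time_ms"].to_numpy())
            trains[int(nid)].append(SpikeTrain(times, duration_ms,
                                               neuron_id=int(nid),
                                               trial_id=int(tid)))
    return trains


def write_spikes_csv(trains: dict, path) -> None:
    trains_to_frame(trains).to_csv(path, index=False)


def read_spikes_csv(path, duration_ms: float) -> dict:
    return frame_to_trains(pd.read_csv(path), duration_ms)


def write_spikes_h5(trains: dict, path, duration_ms: float) -> None:
    df = trains_to_frame(trains)
    with h5py.File(path, "w") as fh:
        fh.attrs["duration_ms"] = duration_ms
        fh.create_dataset("neuron_id", data=df["neuron_id"].to_numpy(np.int64))
        fh.create_dataset("trial_id", data=df["trial_id"].to_numpy(np.int64))
        fh.create_dataset("spike_time_ms",
                          data=df["spike_time_ms"].to_numpy(np.float64))


def read_spikes_h5(path) -> dict:
    with h5py.File(path, "r") as fh:
        df = pd.DataFrame({
            "neuron_id": fh["neuron_id"][...],
            "trial_id": fh["trial_id"][...],
            "spike_time_ms": fh["spike_time_ms"][...],
        })
        duration_ms = float(fh.attrs["duration_ms"])
    return frame_to_trains(df, duration_ms)


def write_manifest(meta: dict, path) -> None:
    """JSON manifest with every parameter and seed needed to re-run."""
    def _default(obj):
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.integer, np.floating)):
            return obj.item()
        return str(obj)

    Path(path).write_text(json.dumps(meta, indent=2, default=_default))
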