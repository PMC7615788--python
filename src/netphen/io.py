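"""Readers and writers for the package's on-disk formats.

MEA recordings travel as HDF5 (dataset ``/signal``, channels x samples in
float32 µV, with sampling/channel metadata in attributes); everything else
is plain text: spike/event/trace CSV, SWC, YAML configs.
"""

from __future__ import annotations

import h5py
import numpy as np
import pandas as pd
import yaml

from .mea import MEARecording, SpikeTrainSet

__all__ = [
    "write_recording_h5",
    "read_recording_h5",
    "write_spikes_csv",
    "read_spikes_csv",
    "write_bursts_csv",
    "write_network_bursts_csv",
    "write_events_csv",
    "read_events_csv",
    "write_trace_csv",
    "read_trace_csv",
    "write_roi_traces_csv",
    "read_roi_traces_csv",
    "load_yaml",
    "dump_yaml",
]


def write_recording_h5(rec: MEARecording, path) -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset("signal", data=rec.signal.astype(np.float32))
        d.attrs["units"] = "uV"
        f.attrs["sampling_rate_hz"] = rec.sampling_rate
        f.attrs["well_id"] = rec.well_id
        f.attrs["channel_ids"] = [str(c) for c in rec.channel_ids]


def read_recording_h5(path) -> MEARecording:
    with h5py.File(path, "r") as f:
        signal = f["signal"][()]
        fs = float(f.attrs["sampling_rate_hz"])
        well = str(f.attrs.get("well_id", "well"))
        channels = [str(c) for c in f.attrs["channel_ids"]]
    return MEARecording(signal, fs, channels, well)


def write_spikes_csv(trains: SpikeTrainSet, path, well: str | None = None) -> None:
    well = well or trains.provenance.get("well_id", "well")
    rows = [
        {"well": well, "channel": ch, "time_s": t}
        for ch, times in trains.trains.items()
        for t in times
    ]
    pd.DataFrame(rows, columns=["well", "channel", "time_s"]).to_csv(path, index=False)


def read_spikes_csv(path, duration: float) -> dict:
    """Returns {well: SpikeTrainSet}. Duration must be supplied: a spike
    table alone does not bound the recording."""
    df = pd.read_csv(path)
    out = {}
    for well, sub in df.groupby("well"):
        trains = {
            str(ch): np.unique(g["time_s"].to_numpy(float))
            for ch, g in sub.groupby("channel")
        }
        out[str(well)] = SpikeTrainSet(trains, duration, {"source": str(path)})
    return out


def write_bursts_csv(bursts_by_channel: dict, path) -> None:
    rows = [
        {"channel": b.channel, "start_s": b.start, "end_s": b.end, "n_spikes": b.n_spikes}
        for bl in bursts_by_channel.values()
        for b in bl
    ]
    pd.DataFrame(rows, columns=["channel", "start_s", "end_s", "n_spikes"]).to_csv(
        path, index=False
    )


def write_network_bursts_csv(network_bursts: list, path) -> None:
    rows = [
        {"start_s": nb.start, "end_s": nb.end,
         "participation": nb.participation,
         "channels": ";".join(sorted(nb.participating_channels))}
        for nb in network_bursts
    ]
    pd.DataFrame(rows, columns=["start_s", "end_s", "participation", "channels"]).to_csv(
        path, index=False
    )


def write_events_csv(events: list, path) -> None:
    rows = [{"time_s": e.onset, "peak_s": e.peak, "amplitude_pA": e.amplitude}
            for e in events]
    pd.DataFrame(rows, columns=["time_s", "peak_s", "amplitude_pA"]).to_csv(
        path, index=False
    )


def read_events_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_trace_csv(time_s: np.ndarray, values: np.ndarray, path,
                    value_col: str = "value") -> None:
    pd.DataFrame({"time_s": time_s, value_col: values}).to_csv(path, index=False)


def read_trace_csv(path, value_col: str | None = None) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path)
    if value_col is None:
        value_col = [c for c in df.columns if c != "time_s"][0]
    return df["time_s"].to_numpy(float), df[value_col].to_numpy(float)


def write_roi_traces_csv(time_s: np.ndarray, traces: np.ndarray, path,
                         roi_ids: list | None = None) -> None:
    roi_ids = roi_ids or [f"roi_{i + 1}" for i in range(traces.shape[0])]
    df = pd.DataFrame({"frame": np.arange(traces.shape[1]), "time_s": time_s})
    for name, row in zip(roi_ids, traces):
        df[name] = row
    df.to_csv(path, index=False)


def read_roi_traces_csv(path) -> tuple[np.ndarray, np.ndarray, list]:
    df = pd.read_csv(path)
    roi_cols = [c for c in df.columns if c not in ("frame", "time_s")]
    return (df["time_s"].to_numpy(float),
            df[roi_cols].to_numpy(float).T, roi_cols)


def load_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def dump_yaml(obj: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=True)
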