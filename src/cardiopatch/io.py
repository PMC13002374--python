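"""Results containers: HDF5 layout and CSV exports.

HDF5 group layout:
  /frames       decimated voltage frames (n_frames, n_elements), float32
  /activation   ragged activation times (flat values + per-element offsets)
  /metrics      scalar readouts as attributes
  /config       normalized run configuration (JSON string attribute)
  /traces       per-probe voltage traces
"""

from __future__ import annotations

import json

import h5py
import numpy as np
import pandas as pd

from . import analysis
from .tissue import SimulationResult

__all__ = [
    "save_result",
    "load_activation",
    "write_trace_csv",
    "read_trace_csv",
    "write_activation_csv",
    "write_remodeling_csv",
]


def save_result(path, result: SimulationResult, metrics: dict | None = None,
                store_frames: bool = False) -> None:
    with h5py.File(path, "w") as f:
        if store_frames and result.frames is not None:
            f.create_dataset(
                "frames", data=result.frames.astype(np.float32),
                compression="gzip", compression_opts=4,
            )
            f.create_dataset("frame_times", data=result.frame_times)
        ev = result.activation.events
        offsets = np.zeros(len(ev) + 1, dtype=np.int64)
        for i, e in enumerate(ev):
            offsets[i + 1] = offsets[i] + len(e)
        values = (np.concatenate(ev) if offsets[-1] else np.empty(0))
        g = f.create_group("activation")
        g.create_dataset("values", data=values)
        g.create_dataset("offsets", data=offsets)
        g.attrs["shape"] = result.activation.shape
        if result.probe_traces is not None:
            tr = f.create_group("traces")
            tr.create_dataset("times", data=result.probe_times)
            tr.create_dataset("v", data=result.probe_traces)
        mg = f.create_group("metrics")
        for k, v in (metrics or {}).items():
            mg.attrs[k] = v
        cg = f.create_group("config")
        cg.attrs["json"] = json.dumps(result.metadata, default=str)
        f.attrs["failed"] = result.failed
        f.attrs["fail_time"] = result.fail_time


def load_activation(path) -> analysis.ActivationMap:
    with h5py.File(path, "r") as f:
        g = f["activation"]
        values = g["values"][...]
        offsets = g["offsets"][...]
        shape = tuple(int(x) for x in g.attrs["shape"])
    events = [values[offsets[i]:offsets[i + 1]] for i in range(len(offsets) - 1)]
    return analysis.ActivationMap(shape=shape, events=events)


def write_trace_csv(path, time, v_m) -> None:
    pd.DataFrame({"time_ms": time, "v_m_mV": v_m}).to_csv(path, index=False)


def read_trace_csv(path):
    df = pd.read_csv(path)
    return df["time_ms"].to_numpy(), df["v_m_mV"].to_numpy()


def write_activation_csv(path, amap: analysis.ActivationMap) -> None:
    ny, nx = amap.shape
    rows = []
    for i, ev in enumerate(amap.events):
        y, x = divmod(i, nx)
        for b, t in enumerate(ev):
            rows.append((x, y, b, t))
    pd.DataFrame(rows, columns=["x", "y", "beat", "t_ms"]).to_csv(path, index=False)


def write_remodeling_csv(path, rmap) -> None:
    rmap.to_dataframe().to_csv(path, index=False)
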