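"""File I/O: meshes (ASCII PLY/OFF), electrode TSV, HDF5 runs, JSON reports.

Coordinates are interpreted as millimetres throughout.  Electrode files
are tab-separated with columns ``name, x_mm, y_mm, z_mm`` ordered from
the innermost contact outward.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import trimesh

from .epileptor import EpileptorParams, SimulationResult
from .forward import SensorSignals
from .mesh import Electrode, TriSurface

__all__ = [
    "read_mesh",
    "write_mesh",
    "read_electrode",
    "write_electrode",
    "save_simulation",
    "load_simulation",
    "save_signals",
    "load_signals",
]


def read_mesh(path) -> TriSurface:
    """Load a triangulated surface from PLY/OFF (or any trimesh format)."""
    m = trimesh.load_mesh(str(path), process=False)
    return TriSurface(np.asarray(m.vertices, float), np.asarray(m.faces, np.int64))


def write_mesh(surface: TriSurface, path) -> None:
    """Write a surface as ASCII PLY or OFF, by file extension."""
    path = Path(path)
    m = trimesh.Trimesh(surface.vertices, surface.triangles, process=False)
    if path.suffix.lower() == ".ply":
        data = trimesh.exchange.ply.export_ply(m, encoding="ascii")
    elif path.suffix.lower() == ".off":
        data = trimesh.exchange.off.export_off(m)
    else:
        raise ValueError(f"unsupported mesh format {path.suffix!r}")
    mode = "wb" if isinstance(data, bytes) else "w"
    with open(path, mode) as f:
        f.write(data)


def write_electrode(electrode: Electrode, path) -> None:
    df = pd.DataFrame(
        {
            "name": electrode.contact_names,
            "x_mm": electrode.contact_positions[:, 0],
            "y_mm": electrode.contact_positions[:, 1],
            "z_mm": electrode.contact_positions[:, 2],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_electrode(path) -> Electrode:
    df = pd.read_csv(path, sep="\t")
    pos = df[["x_mm", "y_mm", "z_mm"]].to_numpy(float)
    if len(pos) >= 2:
        pitch = float(np.median(np.linalg.norm(np.diff(pos, axis=0), axis=1)))
    else:
        pitch = 3.5
    return Electrode(pos, [str(n) for n in df["name"]], pitch=pitch)


def save_simulation(result: SimulationResult, path) -> None:
    """Store a field-simulation result in an HDF5 container."""
    with h5py.File(path, "w") as f:
        f.create_dataset("times", data=result.times)
        f.create_dataset("s", data=result.s, compression="gzip", compression_opts=4)
        if result.u1 is not None:
            f.create_dataset("u1", data=result.u1, compression="gzip", compression_opts=4)
        f.attrs["fs"] = result.fs
        f.attrs["params"] = json.dumps(dataclasses.asdict(result.params))
        f.attrs["meta"] = json.dumps(result.meta)


def load_simulation(path) -> SimulationResult:
    with h5py.File(path, "r") as f:
        params = EpileptorParams(**json.loads(f.attrs["params"]))
        return SimulationResult(
            times=f["times"][:],
            s=f["s"][:],
            fs=float(f.attrs["fs"]),
            params=params,
            u1=f["u1"][:] if "u1" in f else None,
            meta=json.loads(f.attrs["meta"]),
        )


def save_signals(signals: SensorSignals, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("signals", data=signals.signals)
        f.attrs["channel_names"] = json.dumps(list(signals.channel_names))
        f.attrs["fs"] = signals.fs
        f.attrs["referencing"] = signals.referencing
        f.attrs["meta"] = json.dumps(signals.meta)


def load_signals(path) -> SensorSignals:
    with h5py.File(path, "r") as f:
        return SensorSignals(
            signals=f["signals"][:],
            channel_names=json.loads(f.attrs["channel_names"]),
            fs=float(f.attrs["fs"]),
            referencing=str(f.attrs["referencing"]),
            meta=json.loads(f.attrs["meta"]),
        )
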