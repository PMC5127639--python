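"""Configuration files, CSV schemas, mesh export and run manifests."""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .engine import SimConfig, Snapshot, Trajectory, _PHASE_NAMES
from .geometry import ColumnLattice, FTKDPolyhedron
from .honeycomb import TJGraph

__all__ = [
    "load_config", "save_config",
    "write_event_log", "read_event_log",
    "write_snapshots", "read_snapshots",
    "write_off", "write_ply", "write_graph_csv",
    "RunManifest",
]

#: keys a config file must provide (the rest of SimConfig may rely on defaults)
REQUIRED_KEYS = ("wait_max", "disappearance_duration", "dt_minutes",
                 "duration", "seed")


def load_config(path: str | Path, require_complete: bool = True) -> SimConfig:
    """Read a flat key/value YAML simulation config.

    Unknown keys and (when ``require_complete``) missing core keys raise a
    validation error naming the offending key.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError("config must be a flat key/value mapping")
    valid = {f.name for f in dc_fields(SimConfig)}
    for key in raw:
        if key not in valid:
            raise ValueError(f"unknown config key: {key!r}")
    if require_complete:
        for key in REQUIRED_KEYS:
            if key not in raw:
                raise ValueError(f"missing config key: {key!r}")
    return SimConfig(**raw)


def save_config(config: SimConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)


# ---------------------------------------------------------------------------
# CSV schemas
# ---------------------------------------------------------------------------

def write_event_log(traj: Trajectory, path: str | Path) -> None:
    """Event log CSV: time_hr, column_id, event."""
    traj.events.to_csv(path, index=False, float_format="%.6f")


def read_event_log(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_snapshots(traj: Trajectory, path: str | Path,
                    every_hr: float | None = 2.4) -> None:
    """Snapshot CSV: time_hr, column_id, phase, sg2_entry_time omitted
    (heights drive the dynamics), height_thirds.

    ``every_hr`` thins frames; None writes every frame.
    """
    stride = 1 if every_hr is None else max(1, int(round(every_hr / traj.config.dt)))
    rows = []
    n = traj.lattice.n_columns
    for k in range(0, traj.n_frames, stride):
        rows.append(pd.DataFrame({
            "time_hr": np.repeat(traj.times[k], n),
            "column_id": np.arange(n),
            "phase": [_PHASE_NAMES[p] for p in traj.phases[k]],
            "height_thirds": traj.heights3[k],
        }))
    pd.concat(rows, ignore_index=True).to_csv(path, index=False, float_format="%.6f")


def read_snapshots(path: str | Path, lattice: ColumnLattice) -> list[Snapshot]:
    df = pd.read_csv(path)
    inv = {v: k for k, v in _PHASE_NAMES.items()}
    out = []
    for t, grp in df.groupby("time_hr", sort=True):
        grp = grp.sort_values("column_id")
        out.append(Snapshot(float(t),
                            np.array([inv[p] for p in grp["phase"]], dtype=np.int8),
                            grp["height_thirds"].to_numpy(np.int64),
                            lattice))
    return out


def write_graph_csv(graph: TJGraph, path: str | Path) -> None:
    """Honeycomb polygons as a flat vertex table."""
    rows = []
    for p in graph.polygons:
        for k, v in enumerate(p.vertices):
            rows.append({
                "polygon_id": p.poly_id, "column": p.column, "kind": p.kind,
                "vertex": k, "x_um": v[0], "y_um": v[1], "z_um": v[2],
                "seam_class": p.seam_classes[k],
            })
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.6f")


# ---------------------------------------------------------------------------
# mesh export (ASCII OFF / PLY)
# ---------------------------------------------------------------------------

def write_off(cells: list[FTKDPolyhedron], path: str | Path) -> None:
    """ASCII OFF export, one object per call; face classes as comments."""
    verts, faces, classes = _merge_cells(cells)
    with open(path, "w") as fh:
        fh.write("OFF\n")
        fh.write(f"{len(verts)} {len(faces)} 0\n")
        for v in verts:
            fh.write(f"{v[0]:.6f} {v[1]:.6f} {v[2]:.6f}\n")
        for f in faces:
            fh.write(" ".join([str(len(f))] + [str(i) for i in f]) + "\n")
        # face-class table as a trailing comment block (readers that stop
        # after the face list are unaffected)
        for k, cls in enumerate(classes):
            fh.write(f"# face {k} {cls}\n")


def write_ply(cells: list[FTKDPolyhedron], path: str | Path) -> None:
    """ASCII PLY export with polygonal faces and a face class comment table."""
    verts, faces, classes = _merge_cells(cells)
    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        for cls in sorted(set(classes)):
            fh.write(f"comment face_class {cls}\n")
        fh.write(f"element vertex {len(verts)}\n")
        fh.write("property float x\nproperty float y\nproperty float z\n")
        fh.write(f"element face {len(faces)}\n")
        fh.write("property list uchar int vertex_indices\n")
        fh.write("end_header\n")
        for v in verts:
            fh.write(f"{v[0]:.6f} {v[1]:.6f} {v[2]:.6f}\n")
        for f in faces:
            fh.write(" ".join([str(len(f))] + [str(i) for i in f]) + "\n")


def _merge_cells(cells):
    verts, faces, classes = [], [], []
    off = 0
    for c in cells:
        verts.extend(c.vertices.tolist())
        for f in c.faces:
            faces.append([i + off for i in f.indices])
            classes.append(f"{f.kind}:{f.orientation}")
        off += len(c.vertices)
    return verts, faces, classes


# ---------------------------------------------------------------------------
# manifest
# ---------------------------------------------------------------------------

@dataclass
class RunManifest:
    """Inventory of one pipeline invocation."""

    config: dict
    seed: int
    version: str = __version__
    files: dict[str, str] = field(default_factory=dict)  # name -> sha256
    wall_clock_s: float = 0.0

    def add_file(self, path: str | Path) -> None:
        p = Path(path)
        self.files[p.name] = hashlib.sha256(p.read_bytes()).hexdigest()

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump({
                "config": self.config, "seed": self.seed,
                "version": self.version, "files": self.files,
                "wall_clock_s": round(self.wall_clock_s, 3),
            }, fh, indent=2, sort_keys=True)

    @classmethod
    def read(cls, path: str | Path) -> "RunManifest":
        with open(path) as fh:
            d = json.load(fh)
        return cls(config=d["config"], seed=d["seed"], version=d["version"],
                   files=d["files"], wall_clock_s=d["wall_clock_s"])


def timed(fn, *args, **kwargs):
    t0 = time.perf_counter()
    out = fn(*args, **kwargs)
    return out, time.perf_counter() - t0
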