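"""File formats and run configuration.

Meshes travel as STL/PLY/OBJ (mm); markers as CSV with mandatory columns
``label,x,y,z,frame`` (the frame tag prevents motion-capture coordinates
from being mistaken for CT ones — the frame-transfer step is where real
sessions go wrong); TRC motion-capture exports can be imported.  Results
are JSON with the resolved configuration and seed embedded, so any output
can be reproduced from itself.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh
import yaml

from .surface_model import MARKER_FRAMES, MarkerSet

__all__ = [
    "RunConfig",
    "read_mesh",
    "write_mesh",
    "read_markers",
    "write_markers",
    "read_trc",
    "write_trc",
    "write_json",
]

_MESH_EXTS = {".stl", ".ply", ".obj"}


class MarkerParseError(ValueError):
    """Malformed marker file; carries the offending row when known."""


@dataclass(frozen=True)
class RunConfig:
    """Method parameters; defaults are the selected calibration condition.

    target edge 3 mm, soft-tissue threshold 0-20 mm, marker minimum
    distance 10 mm, step h = 0.5 mm/degree, sequential updates, ±10 mm/deg
    initial-pose perturbation in simulation runs.
    """

    target_edge_mm: float = 3.0
    thickness_range_mm: tuple[float, float] = (0.0, 20.0)
    marker_min_distance_mm: float = 10.0
    h: float = 0.5
    max_sweeps: int = 10_000
    update_mode: str = "sequential"
    perturbation_mm_deg: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "thickness_range_mm",
            (float(self.thickness_range_mm[0]), float(self.thickness_range_mm[1])),
        )
        if self.update_mode not in ("sequential", "simultaneous"):
            raise ValueError("update_mode must be 'sequential' or 'simultaneous'")
        if self.h <= 0 or self.max_sweeps < 1:
            raise ValueError("h must be > 0 and max_sweeps >= 1")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["thickness_range_mm"] = list(self.thickness_range_mm)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {k: v for k, v in d.items() if k in cls.__dataclass_fields__}
        unknown = set(d) - set(known)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "thickness_range_mm" in known:
            known["thickness_range_mm"] = tuple(known["thickness_range_mm"])
        return cls(**known)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as f:
            data = yaml.safe_load(f) or {}
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as f:
            yaml.safe_dump(self.to_dict(), f, sort_keys=False)

    def with_seed(self, seed: int) -> "RunConfig":
        return replace(self, seed=int(seed))


# ---------------------------------------------------------------------------
# Meshes
# ---------------------------------------------------------------------------

def read_mesh(path) -> trimesh.Trimesh:
    """Load an STL/PLY/OBJ mesh (mm).

    STL stores an unindexed triangle soup, so exactly coincident vertices
    are merged back into a shared-vertex mesh; indexed formats are loaded
    as-is.
    """
    path = Path(path)
    ext = path.suffix.lower()
    if ext not in _MESH_EXTS:
        raise ValueError(f"unsupported mesh format {ext!r} (use STL/PLY/OBJ)")
    try:
        mesh = trimesh.load_mesh(str(path), process=False)
    except Exception as e:  # noqa: BLE001
        raise ValueError(f"cannot parse mesh file {path}: {e}") from e
    if isinstance(mesh, trimesh.Scene):
        geoms = list(mesh.geometry.values())
        if not geoms:
            raise ValueError(f"mesh file {path} contains no geometry")
        mesh = geoms[0]
    if mesh.vertices.shape[0] == 0 or mesh.faces.shape[0] == 0:
        raise ValueError(f"mesh file {path} contains no triangles")
    if ext == ".stl":
        mesh = _merge_exact_vertices(mesh)
    return trimesh.Trimesh(np.asarray(mesh.vertices, float),
                           np.asarray(mesh.faces, int), process=False)


def _merge_exact_vertices(mesh: trimesh.Trimesh) -> trimesh.Trimesh:
    v = np.asarray(mesh.vertices, float)
    uniq, inverse = np.unique(v, axis=0, return_inverse=True)
    return trimesh.Trimesh(uniq, inverse[np.asarray(mesh.faces, int)], process=False)


def write_mesh(mesh: trimesh.Trimesh, path, ascii_stl: bool = False) -> None:
    """Write a mesh by extension (STL binary by default, or ASCII)."""
    path = Path(path)
    ext = path.suffix.lower()
    if ext not in _MESH_EXTS:
        raise ValueError(f"unsupported mesh format {ext!r} (use STL/PLY/OBJ)")
    if ext == ".stl" and ascii_stl:
        path.write_text(
            trimesh.exchange.stl.export_stl_ascii(mesh)
        )
        return
    mesh.export(str(path))


# ---------------------------------------------------------------------------
# Markers
# ---------------------------------------------------------------------------

def read_markers(path) -> MarkerSet:
    """Read a marker CSV with header ``label,x,y,z,frame``."""
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as e:  # noqa: BLE001
        raise MarkerParseError(f"cannot parse marker CSV {path}: {e}") from e
    required = ["label", "x", "y", "z", "frame"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise MarkerParseError(f"{path}: missing columns {missing}")
    for col in ("x", "y", "z"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        if coerced.isna().any():
            row = int(coerced.isna().idxmax()) + 2  # header + 1-based
            raise MarkerParseError(
                f"{path}: non-numeric {col!r} value at line {row}"
            )
        df[col] = coerced
    frames = df["frame"].astype(str).unique()
    if len(frames) != 1:
        raise MarkerParseError(f"{path}: mixed frame tags {sorted(frames)}")
    frame = frames[0]
    if frame not in MARKER_FRAMES:
        raise MarkerParseError(
            f"{path}: frame must be one of {MARKER_FRAMES}, got {frame!r}"
        )
    return MarkerSet(df[["x", "y", "z"]].to_numpy(float),
                     tuple(df["label"].astype(str)), frame)


def write_markers(markers: MarkerSet, path) -> None:
    df = pd.DataFrame(
        {
            "label": markers.labels,
            "x": markers.coords[:, 0],
            "y": markers.coords[:, 1],
            "z": markers.coords[:, 2],
            "frame": markers.frame,
        }
    )
    df.to_csv(path, index=False, float_format="%.17g")  # lossless round trip


def read_trc(path, frame: str = "mocap", time_index: int = 0) -> MarkerSet:
    """Import one frame of a TRC motion-capture export.

    TRC is a tab-separated text format: three header lines of metadata, a
    marker-name row (names every third column starting at column 3), a
    coordinate-axis row, then one row per captured time sample.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if len(lines) < 6:
        raise MarkerParseError(f"{path}: truncated TRC file")
    name_row = lines[3].rstrip("\n").split("\t")
    labels = [c for c in name_row[2:] if c.strip()]
    data_lines = [ln for ln in lines[5:] if ln.strip()]
    if time_index >= len(data_lines):
        raise MarkerParseError(f"{path}: no data row {time_index}")
    fields = data_lines[time_index].split("\t")
    coords = []
    for j, label in enumerate(labels):
        cols = fields[2 + 3 * j: 5 + 3 * j]
        if len(cols) < 3:
            raise MarkerParseError(f"{path}: marker {label!r} has missing columns")
        try:
            coords.append([float(c) for c in cols])
        except ValueError as e:
            raise MarkerParseError(
                f"{path}: non-numeric coordinate for marker {label!r}"
            ) from e
    return MarkerSet(np.array(coords), tuple(labels), frame)


def write_trc(markers: MarkerSet, path, data_rate: float = 100.0) -> None:
    """Write a single-sample TRC file (synthetic export, for round-trips)."""
    path = Path(path)
    m = markers.m
    head = [
        f"PathFileType\t4\t(X/Y/Z)\t{path.name}",
        "DataRate\tCameraRate\tNumFrames\tNumMarkers\tUnits\tOrigDataRate\t"
        "OrigDataStartFrame\tOrigNumFrames",
        f"{data_rate}\t{data_rate}\t1\t{m}\tmm\t{data_rate}\t1\t1",
        "Frame#\tTime\t" + "\t\t\t".join(markers.labels) + "\t\t",
        "\t\t" + "\t".join(
            f"X{i + 1}\tY{i + 1}\tZ{i + 1}" for i in range(m)
        ),
    ]
    row = "1\t0.000\t" + "\t".join(
        f"{v:.6f}" for v in markers.coords.ravel()
    )
    path.write_text("\n".join(head + [row]) + "\n")


def write_json(payload: dict, path) -> None:
    with open(path, "w") as f:
        json.dump(payload, f, indent=2, default=_json_default)
        f.write("\n")


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
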