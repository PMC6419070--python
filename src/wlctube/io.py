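"""Trajectory persistence: CSV extension series, JSON metadata, XYZ frames."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np

from . import __version__
from .errors import TrajectoryParseError
from .gbr import Hydrodynamics, IntegratorParams, Trajectory
from .theory import ChannelGeometry, ChannelKind


def write_trajectory(traj: Trajectory, prefix: "str | Path") -> "dict[str, Path]":
    """Write a trajectory as ``<prefix>.csv`` + ``<prefix>.json``
    (+ ``<prefix>.xyz`` when frames were recorded).  Returns the paths."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    csv_path = prefix.with_suffix(".csv")
    json_path = prefix.with_suffix(".json")
    steps = np.arange(len(traj.extension)) * traj.record_every
    with open(csv_path, "w") as fh:
        fh.write("step,extension_nm\n")
        for s, e in zip(steps, traj.extension):
            fh.write(f"{s},{e:.10g}\n")
    meta = traj.metadata()
    meta["version"] = __version__
    with open(json_path, "w") as fh:
        json.dump(meta, fh, indent=1)
    out = {"csv": csv_path, "json": json_path}
    if traj.frames is not None:
        xyz_path = prefix.with_suffix(".xyz")
        write_xyz(traj.frames, xyz_path)
        out["xyz"] = xyz_path
    return out


def read_trajectory(prefix: "str | Path") -> Trajectory:
    """Read a trajectory written by :func:`write_trajectory`."""
    prefix = Path(prefix)
    csv_path = prefix.with_suffix(".csv")
    json_path = prefix.with_suffix(".json")
    with open(json_path) as fh:
        meta = json.load(fh)

    ext = []
    expected_step = None
    with open(csv_path) as fh:
        header = fh.readline().strip()
        if header != "step,extension_nm":
            raise TrajectoryParseError(f"bad header {header!r}", csv_path, 1)
        for ln, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            parts = line.split(",")
            if len(parts) != 2:
                raise TrajectoryParseError(f"expected 2 fields, got {len(parts)}", csv_path, ln)
            try:
                s = int(parts[0])
                e = float(parts[1])
            except ValueError as exc:
                raise TrajectoryParseError(str(exc), csv_path, ln) from None
            if expected_step is not None and s != expected_step:
                raise TrajectoryParseError(
                    f"non-contiguous steps ({s} after {expected_step - meta['record_every']})",
                    csv_path,
                    ln,
                )
            expected_step = s + meta["record_every"]
            ext.append(e)
    if len(ext) != meta["n_recorded"]:
        raise TrajectoryParseError(
            f"truncated series: {len(ext)} rows, metadata says {meta['n_recorded']}",
            csv_path,
            None,
        )

    geom = None
    if meta["geometry"] is not None:
        g = meta["geometry"]
        geom = ChannelGeometry(g["Hh"], g["Hw"], ChannelKind(g["kind"]))
    p = meta["params"]
    params = IntegratorParams(
        dt=p["dt"],
        steps=p["steps"],
        seed=p["seed"],
        temperature=p["temperature"],
        viscosity=p["viscosity"],
        hydrodynamics=Hydrodynamics(p["hydrodynamics"]),
    )
    frames = None
    xyz_path = prefix.with_suffix(".xyz")
    if xyz_path.exists():
        frames = read_xyz(xyz_path)
    return Trajectory(
        extension=np.asarray(ext),
        record_every=meta["record_every"],
        params=params,
        f_hat=meta["f_hat"],
        geometry=geom,
        chain_b=meta["chain"]["b"],
        chain_a=meta["chain"]["a"],
        chain_Lp=meta["chain"]["Lp"],
        chain_N=meta["chain"]["N"],
        max_rod_error=meta["max_rod_error"],
        max_wall_violation=meta["max_wall_violation"],
        frames=frames,
    )


def write_xyz(frames: np.ndarray, path: "str | Path", comment: str = "wlctube frame") -> None:
    """Frames of bead positions as a multi-frame XYZ file (element 'C')."""
    frames = np.asarray(frames)
    with open(path, "w") as fh:
        for f in frames:
            fh.write(f"{len(f)}\n{comment}\n")
            for x, y, z in f:
                fh.write(f"C {x:.6f} {y:.6f} {z:.6f}\n")


def read_xyz(path: "str | Path") -> np.ndarray:
    """Read a multi-frame XYZ file back into an (n_frames, N, 3) array."""
    frames = []
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    ln = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            natoms = int(lines[i].strip())
        except ValueError:
            raise TrajectoryParseError("expected atom count", path, i + 1) from None
        if i + 1 + natoms >= len(lines) + 1:
            raise TrajectoryParseError("truncated frame", path, i + 1)
        block = lines[i + 2 : i + 2 + natoms]
        if len(block) != natoms:
            raise TrajectoryParseError("truncated frame", path, i + 1)
        coords = []
        for j, row in enumerate(block):
            parts = row.split()
            if len(parts) != 4:
                raise TrajectoryParseError("expected 'El x y z'", path, i + 3 + j)
            coords.append([float(v) for v in parts[1:]])
        frames.append(coords)
        i += 2 + natoms
    return np.asarray(frames)
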