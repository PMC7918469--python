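"""Trajectory persistence: extended-XYZ frames plus a CSV scalar sidecar.

Each frame is stored as

    N
    Lattice="Lx 0 0 0 Ly 0 0 0 Lz" Properties=species:S:1:pos:R:3:quat:R:4:vel:R:3:angmom:R:3 Time=t*
    <species> x y z qw qx qy qz vx vy vz lx ly lz

with full float precision, so a write/read round trip is bit-identical on
all stored fields.  Per-frame scalars (potential energy, kinetic
temperatures, pressure tensor) live in a sibling CSV; an HDF5 container
with the identical schema is also provided.
"""

from __future__ import annotations

import re
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .engine import State, Trajectory

__all__ = [
    "TrajectoryParseError",
    "write_trajectory",
    "read_trajectory",
    "write_trajectory_h5",
    "read_trajectory_h5",
    "scalars_path_for",
]

_PROPERTIES = "species:S:1:pos:R:3:quat:R:4:vel:R:3:angmom:R:3"
_REQUIRED_FIELDS = ("pos", "quat", "vel", "angmom")


class TrajectoryParseError(ValueError):
    """Malformed trajectory file; carries the offending frame index."""

    def __init__(self, message: str, frame: int):
        super().__init__(f"frame {frame}: {message}")
        self.frame = frame


def scalars_path_for(path) -> Path:
    p = Path(path)
    return p.with_name(p.stem + "_scalars.csv")


def write_trajectory(traj: Trajectory, path, scalars_path=None) -> None:
    path = Path(path)
    box = [float(x) for x in traj.box]
    lattice = f"{box[0]!r} 0 0 0 {box[1]!r} 0 0 0 {box[2]!r}"
    with open(path, "w") as fh:
        for fr in traj:
            fh.write(f"{fr.n_particles}\n")
            catalog = " ".join(traj.species_names)
            fh.write(
                f'Lattice="{lattice}" Properties={_PROPERTIES} '
                f'Species="{catalog}" Time={float(fr.time)!r}\n'
            )
            for k in range(fr.n_particles):
                name = fr.species_names[fr.species_index[k]]
                nums = np.concatenate(
                    [fr.positions[k], fr.orientations[k], fr.velocities[k], fr.ang_momenta[k]]
                )
                fh.write(name + " " + " ".join(repr(float(x)) for x in nums) + "\n")
    if scalars_path is None:
        scalars_path = scalars_path_for(path)
    traj.scalars.to_csv(scalars_path, index=False)


def _parse_header(line: str, frame: int) -> tuple[np.ndarray, float, str]:
    m = re.search(r'Lattice="([^"]+)"', line)
    if m is None:
        raise TrajectoryParseError("missing Lattice entry", frame)
    cell = np.fromstring(m.group(1), sep=" ")
    if cell.size != 9:
        raise TrajectoryParseError("Lattice must hold 9 numbers", frame)
    box = cell.reshape(3, 3).diagonal().copy()
    m = re.search(r"Properties=(\S+)", line)
    if m is None:
        raise TrajectoryParseError("missing Properties entry", frame)
    props = m.group(1)
    for fieldname in _REQUIRED_FIELDS:
        if f"{fieldname}:R" not in props:
            raise TrajectoryParseError(f"missing required field {fieldname!r}", frame)
    m = re.search(r"Time=(\S+)", line)
    time = float(m.group(1)) if m else float(frame)
    m = re.search(r'Species="([^"]*)"', line)
    species = m.group(1).split() if m else None
    return box, time, props, species


def read_trajectory(path, scalars_path=None, species_names=None) -> Trajectory:
    """Read an extended-XYZ trajectory (and its scalar sidecar when present).

    With ``species_names`` given, any species label outside that catalog is
    an error; otherwise the catalog is collected from the file in order of
    first appearance.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    pos = 0
    frames: list[dict] = []
    known: list[str] = list(species_names) if species_names is not None else []
    closed_catalog = species_names is not None
    fidx = 0
    box = None
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        try:
            n = int(lines[pos].strip())
        except ValueError:
            raise TrajectoryParseError("expected particle count", fidx) from None
        if pos + 1 >= len(lines):
            raise TrajectoryParseError("truncated: missing header line", fidx)
        fbox, time, _, declared = _parse_header(lines[pos + 1], fidx)
        if box is None:
            box = fbox
        if declared and not closed_catalog:
            for nm in declared:
                if nm not in known:
                    known.append(nm)
        rows = lines[pos + 2 : pos + 2 + n]
        if len(rows) < n:
            raise TrajectoryParseError(f"truncated: expected {n} particle rows", fidx)
        names = []
        data = np.empty((n, 13))
        for k, row in enumerate(rows):
            parts = row.split()
            if len(parts) != 14:
                raise TrajectoryParseError(
                    f"particle row has {len(parts)} columns, expected 14", fidx
                )
            names.append(parts[0])
            data[k] = [float(x) for x in parts[1:]]
        for nm in names:
            if nm not in known:
                if closed_catalog:
                    raise TrajectoryParseError(f"species label {nm!r} not in catalog", fidx)
                known.append(nm)
        sidx = np.array([known.index(nm) for nm in names], dtype=np.intp)
        frames.append(
            {"time": time, "box": fbox, "species_index": sidx, "data": data}
        )
        pos += 2 + n
        fidx += 1
    if not frames:
        raise TrajectoryParseError("no frames found", 0)
    traj = Trajectory(tuple(known), box)
    for fr in frames:
        d = fr["data"]
        traj.append(
            State(
                box=fr["box"],
                positions=d[:, 0:3],
                orientations=d[:, 3:7],
                velocities=d[:, 7:10],
                ang_momenta=d[:, 10:13],
                species_index=fr["species_index"],
                species_names=tuple(known),
                time=fr["time"],
            )
        )
    if scalars_path is None:
        candidate = scalars_path_for(path)
        scalars_path = candidate if candidate.exists() else None
    if scalars_path is not None:
        df = pd.read_csv(scalars_path)
        if len(df):
            traj._scalars = df.to_dict("records")
    return traj


# ---------------------------------------------------------------------------
# HDF5 container (identical schema)
# ---------------------------------------------------------------------------

def write_trajectory_h5(traj: Trajectory, path) -> None:
    with h5py.File(path, "w") as h5:
        h5.attrs["species_names"] = [nm.encode() for nm in traj.species_names]
        h5.attrs["metadata"] = yaml.safe_dump(traj.metadata)
        h5.create_dataset("box", data=traj.box)
        h5.create_dataset("times", data=traj.times)
        h5.create_dataset("species_index", data=traj[0].species_index)
        for name, attr in (
            ("positions", "positions"),
            ("orientations", "orientations"),
            ("velocities", "velocities"),
            ("ang_momenta", "ang_momenta"),
        ):
            h5.create_dataset(name, data=np.stack([getattr(f, attr) for f in traj]))
        grp = h5.create_group("scalars")
        for col in traj.scalars.columns:
            grp.create_dataset(col, data=traj.scalars[col].to_numpy())


def read_trajectory_h5(path) -> Trajectory:
    with h5py.File(path, "r") as h5:
        names = tuple(
            nm.decode() if isinstance(nm, bytes) else str(nm)
            for nm in h5.attrs["species_names"]
        )
        box = h5["box"][...]
        times = h5["times"][...]
        sidx = h5["species_index"][...].astype(np.intp)
        traj = Trajectory(names, box, metadata=yaml.safe_load(h5.attrs["metadata"]))
        scalars = {k: h5["scalars"][k][...] for k in h5["scalars"]}
        for i, t in enumerate(times):
            traj.append(
                State(
                    box=box,
                    positions=h5["positions"][i],
                    orientations=h5["orientations"][i],
                    velocities=h5["velocities"][i],
                    ang_momenta=h5["ang_momenta"][i],
                    species_index=sidx,
                    species_names=names,
                    time=float(t),
                ),
                {k: v[i] for k, v in scalars.items() if k != "time"},
            )
    return traj
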