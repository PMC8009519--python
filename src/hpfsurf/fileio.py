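"""GRO and XYZ readers/writers plus run manifests.

GRO carries a single configuration with fixed-width columns (positions in
nm at 3 decimals, optional velocities in nm/ps at 4 decimals) and is used
for initial/final configurations; multi-frame XYZ (nm, time stamp in the
comment line) is the lightweight trajectory format.  The GRO residue field
is only 5 digits wide, so molecule ids are written modulo 100000 and
recovered on read by change detection — systems here can exceed 180 000
solvent beads.
"""

from __future__ import annotations

import hashlib
import json
import time as _time
from pathlib import Path
from typing import List, Optional, Sequence

import numpy as np

from .forcefield import BEAD_MASSES
from .system import SystemState, Trajectory, unwrap_trajectory

__all__ = [
    "read_gro", "write_gro",
    "read_xyz_trajectory", "write_xyz_trajectory",
    "write_manifest",
]


class FileFormatError(ValueError):
    pass


def write_gro(state: SystemState, path, title: str = "hpfsurf configuration") -> None:
    """Write a fixed-width GRO file (positions nm, velocities nm/ps)."""
    path = Path(path)
    names = (state.molecule_name if state.molecule_name is not None
             else np.array(["MOL"] * state.n_particles))
    has_vel = state.velocities is not None and np.any(state.velocities)
    with open(path, "w") as fh:
        fh.write(f"{title}, t= {state.time:.3f}\n")
        fh.write(f"{state.n_particles:d}\n")
        for i in range(state.n_particles):
            resid = (int(state.molecule_id[i]) + 1) % 100000
            x, y, z = state.positions[i]
            line = (f"{resid:5d}{str(names[i])[:5]:<5s}"
                    f"{str(state.species[i])[:5]:>5s}{(i + 1) % 100000:5d}"
                    f"{x:8.3f}{y:8.3f}{z:8.3f}")
            if has_vel:
                vx, vy, vz = state.velocities[i]
                line += f"{vx:8.4f}{vy:8.4f}{vz:8.4f}"
            fh.write(line + "\n")
        L = state.box_edge
        fh.write(f"{L:10.5f}{L:10.5f}{L:10.5f}\n")


def read_gro(path) -> SystemState:
    """Parse a GRO file; raises FileFormatError naming the offending line."""
    path = Path(path)
    lines = path.read_text().splitlines()
    if len(lines) < 3:
        raise FileFormatError(f"{path}: fewer than 3 lines; not a GRO file")
    title = lines[0]
    try:
        n = int(lines[1].strip())
    except ValueError:
        raise FileFormatError(f"{path}:2: atom count {lines[1]!r} is not an integer")
    if len(lines) < n + 3:
        raise FileFormatError(
            f"{path}: expected {n} atom lines plus a box line, found "
            f"{len(lines) - 2} lines after the header (missing box line?)")
    time = 0.0
    if "t=" in title:
        try:
            time = float(title.split("t=")[1].split()[0].rstrip(","))
        except (IndexError, ValueError):
            pass

    pos = np.empty((n, 3))
    vel = np.zeros((n, 3))
    species: List[str] = []
    names: List[str] = []
    mol_id = np.empty(n, dtype=int)
    prev_resid = None
    mol_counter = -1
    for k in range(n):
        lineno = k + 3
        line = lines[k + 2]
        if len(line) < 44:
            raise FileFormatError(f"{path}:{lineno}: atom line too short")
        try:
            resid = int(line[0:5])
            resname = line[5:10].strip()
            atomname = line[10:15].strip()
            pos[k] = [float(line[20:28]), float(line[28:36]), float(line[36:44])]
            if len(line.rstrip()) >= 68:
                vel[k] = [float(line[44:52]), float(line[52:60]), float(line[60:68])]
        except ValueError as e:
            raise FileFormatError(f"{path}:{lineno}: malformed atom line ({e})")
        if resid != prev_resid:
            mol_counter += 1
            prev_resid = resid
        mol_id[k] = mol_counter
        species.append(atomname)
        names.append(resname)

    box_line = lines[n + 2].split()
    try:
        box = [float(x) for x in box_line[:3]]
    except (ValueError, IndexError):
        raise FileFormatError(f"{path}:{n + 3}: malformed box line {lines[n + 2]!r}")
    if len(box) < 3 or box[0] <= 0:
        raise FileFormatError(f"{path}:{n + 3}: missing or invalid box vector")

    species_arr = np.array(species)
    mass = np.array([BEAD_MASSES.get(s, 1.0) for s in species])
    return SystemState(
        box_edge=box[0], positions=pos, velocities=vel, species=species_arr,
        molecule_id=mol_id, time=time, mass=mass,
        molecule_name=np.array(names),
    )


def write_xyz_trajectory(traj: Trajectory, path, wrapped: bool = True,
                         precision: int = 5, angstrom: bool = False) -> None:
    """Multi-frame XYZ with per-frame time stamps in the comment line.

    Default unit is nm (recorded in the comment); ``angstrom=True`` writes
    conventional Angstrom XYZ for viewers that assume it.
    """
    path = Path(path)
    scale = 10.0 if angstrom else 1.0
    unit = "A" if angstrom else "nm"
    coords = traj.positions if wrapped else traj.unwrapped
    fmt = f"{{:.{precision}f}}"
    with open(path, "w") as fh:
        for fi in range(traj.n_frames):
            fh.write(f"{traj.n_particles}\n")
            fh.write(f"t= {traj.times[fi]:.6f} ps "
                     f"box= {traj.box_edge * scale:.5f} {unit} "
                     f"units= {unit} wrapped= {wrapped}\n")
            for i in range(traj.n_particles):
                x, y, z = coords[fi, i] * scale
                fh.write(f"{str(traj.species[i]):<4s} "
                         f"{fmt.format(x)} {fmt.format(y)} {fmt.format(z)}\n")


def read_xyz_trajectory(path, box_edge: Optional[float] = None) -> Trajectory:
    """Parse a multi-frame XYZ trajectory written in nm.

    Wrapped coordinates are unwrapped by chaining minimum-image
    displacements between consecutive frames.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise FileFormatError(f"{path}: empty file")
    frames = []
    times = []
    species: Optional[List[str]] = None
    box = box_edge
    k = 0
    while k < len(lines):
        if not lines[k].strip():
            k += 1
            continue
        try:
            n = int(lines[k].strip())
        except ValueError:
            raise FileFormatError(f"{path}:{k + 1}: expected atom count, got "
                                  f"{lines[k]!r}")
        comment = lines[k + 1] if k + 1 < len(lines) else ""
        t = len(times) * 1.0
        if "t=" in comment:
            try:
                t = float(comment.split("t=")[1].split()[0])
            except (IndexError, ValueError):
                pass
        if "box=" in comment and box_edge is None:
            try:
                box = float(comment.split("box=")[1].split()[0])
                if "units= A" in comment:
                    box *= 0.1
            except (IndexError, ValueError):
                pass
        if k + 2 + n > len(lines):
            raise FileFormatError(f"{path}:{k + 1}: truncated frame")
        scale = 0.1 if "units= A" in comment else 1.0
        labels = []
        coords = np.empty((n, 3))
        for i in range(n):
            parts = lines[k + 2 + i].split()
            if len(parts) < 4:
                raise FileFormatError(f"{path}:{k + 3 + i}: malformed atom line")
            labels.append(parts[0])
            coords[i] = [float(parts[1]) * scale, float(parts[2]) * scale,
                         float(parts[3]) * scale]
        if species is None:
            species = labels
        elif len(labels) != len(species):
            raise FileFormatError(
                f"{path}:{k + 1}: inconsistent atom count across frames "
                f"({len(labels)} vs {len(species)})")
        frames.append(coords)
        times.append(t)
        k += 2 + n
    if box is None:
        raise FileFormatError(f"{path}: no box edge in comments; pass box_edge")
    wrapped = np.mod(np.array(frames), box)
    return Trajectory(
        box_edge=box, times=np.array(times), positions=wrapped,
        unwrapped=unwrap_trajectory(wrapped, box),
        species=np.array(species),
        molecule_id=np.arange(len(species)),
        mass=np.array([BEAD_MASSES.get(s, 1.0) for s in species]),
    )


def _digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(path, config: dict, seed: Optional[int] = None,
                   inputs: Sequence = (), outputs: Sequence = ()) -> dict:
    """Write a JSON provenance manifest next to an analysis output."""
    from . import __version__
    manifest = {
        "code_version": __version__,
        "timestamp": _time.strftime("%Y-%m-%dT%H:%M:%S"),
        "seed": seed,
        "config": config,
        "inputs": {str(p): _digest(p) for p in inputs if Path(p).exists()},
        "outputs": {str(p): _digest(p) for p in outputs if Path(p).exists()},
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
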