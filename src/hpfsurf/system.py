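"""In-memory containers for configurations and trajectories.

Coordinates are stored in nm with the periodic box origin at a corner;
wrapped positions live in the half-open interval [0, L).  Trajectories
additionally carry unwrapped coordinates so that mean-square displacements
can be computed without re-unwrapping.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = ["SystemState", "Trajectory", "wrap_positions", "minimum_image"]


def wrap_positions(pos: np.ndarray, box_edge: float) -> np.ndarray:
    """Wrap coordinates into [0, box_edge)."""
    return np.mod(pos, box_edge)


def minimum_image(disp: np.ndarray, box_edge: float) -> np.ndarray:
    """Minimum-image convention for displacement vectors."""
    return disp - box_edge * np.round(disp / box_edge)


@dataclass
class SystemState:
    """One time frame of a periodic particle system."""

    box_edge: float
    positions: np.ndarray          # (N, 3) nm, wrapped
    velocities: np.ndarray         # (N, 3) nm/ps
    species: np.ndarray            # (N,) str labels
    molecule_id: np.ndarray        # (N,) int, contiguous per molecule
    time: float = 0.0
    mass: Optional[np.ndarray] = None        # (N,) amu
    charge: Optional[np.ndarray] = None      # (N,) e
    molecule_name: Optional[np.ndarray] = None  # (N,) str

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.velocities = np.asarray(self.velocities, dtype=float)
        self.species = np.asarray(self.species)
        self.molecule_id = np.asarray(self.molecule_id, dtype=int)

    @property
    def n_particles(self) -> int:
        return len(self.positions)

    @property
    def n_molecules(self) -> int:
        return len(np.unique(self.molecule_id))

    def copy(self) -> "SystemState":
        return SystemState(
            box_edge=self.box_edge,
            positions=self.positions.copy(),
            velocities=self.velocities.copy(),
            species=self.species.copy(),
            molecule_id=self.molecule_id.copy(),
            time=self.time,
            mass=None if self.mass is None else self.mass.copy(),
            charge=None if self.charge is None else self.charge.copy(),
            molecule_name=(None if self.molecule_name is None
                           else self.molecule_name.copy()),
        )


@dataclass
class Trajectory:
    """A stack of frames sharing one topology.

    ``positions`` are wrapped, ``unwrapped`` are the continuous coordinates
    (equal to ``positions`` plus accumulated box crossings).
    """

    box_edge: float
    times: np.ndarray              # (F,) ps
    positions: np.ndarray          # (F, N, 3) wrapped
    unwrapped: np.ndarray          # (F, N, 3)
    species: np.ndarray            # (N,)
    molecule_id: np.ndarray        # (N,)
    mass: Optional[np.ndarray] = None
    molecule_name: Optional[np.ndarray] = None
    ground_truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.unwrapped is None:
            self.unwrapped = unwrap_trajectory(self.positions, self.box_edge)
        self.unwrapped = np.asarray(self.unwrapped, dtype=float)

    @property
    def n_frames(self) -> int:
        return len(self.times)

    @property
    def n_particles(self) -> int:
        return self.positions.shape[1]

    def frame(self, i: int) -> SystemState:
        return SystemState(
            box_edge=self.box_edge,
            positions=self.positions[i],
            velocities=np.zeros_like(self.positions[i]),
            species=self.species,
            molecule_id=self.molecule_id,
            time=float(self.times[i]),
            mass=self.mass,
            molecule_name=self.molecule_name,
        )


def unwrap_trajectory(wrapped: np.ndarray, box_edge: float) -> np.ndarray:
    """Recover continuous coordinates by chaining minimum-image displacements.

    Valid as long as no particle moves more than half a box edge between
    consecutive frames.
    """
    wrapped = np.asarray(wrapped, dtype=float)
    steps = np.diff(wrapped, axis=0)
    steps = minimum_image(steps, box_edge)
    out = np.empty_like(wrapped)
    out[0] = wrapped[0]
    np.cumsum(steps, axis=0, out=steps)
    out[1:] = wrapped[0] + steps
    return out
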