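"""Initial-configuration builder and synthetic fixtures.

Translates a (concentration, box edge, solvent) specification into a
particle system: the number of surfactant molecules follows directly from
the molarity, and the solvent fills the remaining volume at its bulk bead
density.  The module also provides two synthetic generators used throughout
the test suite and the analysis stages:

* planted cluster configurations with a known ground-truth partition, for
  validating the cluster detector, and
* ideal Brownian trajectories with a known diffusion coefficient, for
  validating the Einstein-relation fit.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .forcefield import BEAD_MASSES, ForceField
from .system import SystemState, Trajectory, wrap_positions
from .units import KB, NA

__all__ = [
    "SystemSpec",
    "molecule_count",
    "solvent_count",
    "build_system",
    "make_planted_clusters",
    "make_brownian_trajectory",
]

#: Bulk bead-filling densities (molecules/nm^3) and bead mappings.
WATER_DENSITY = 33.33        # H2O molecules per nm^3
WATER_MAPPING = 4            # molecules per bead
CYCLOHEXANE_DENSITY = 5.58   # C6H12 molecules per nm^3
CYCLOHEXANE_MAPPING = 1
#: Volume displaced by one surfactant molecule, nm^3.
V_ADOH = 0.89

#: Minimum inter-bead distance during random sequential placement, nm.
MIN_PLACEMENT_DIST = 0.25

SOLVENT_NAMES = {"W": "SOL", "C": "CHX"}


@dataclass(frozen=True)
class SystemSpec:
    """Recipe for one simulated system."""

    concentration: float        # mM
    box_edge: float             # nm
    solvent: str                # "W" or "C"
    seed: int = 0
    temperature: float = 300.0  # K

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise ValueError("concentration must be nonnegative")
        if self.box_edge <= 0:
            raise ValueError("box_edge must be positive")
        if self.solvent not in SOLVENT_NAMES:
            raise ValueError(f"unknown solvent {self.solvent!r}")


def molecule_count(concentration: float, box_edge: float) -> int:
    """Number of solute molecules at a molar concentration in a cubic box.

    ``concentration`` in mM, ``box_edge`` in nm.  The count is
    round-to-nearest of c * N_A * V with V converted to liters
    (1 nm^3 = 1e-24 L).
    """
    if concentration < 0 or box_edge < 0:
        raise ValueError("inputs must be nonnegative")
    n = concentration * 1e-3 * NA * box_edge**3 * 1e-24
    return int(math.floor(n + 0.5))


def solvent_count(box_edge: float, n_solute: int, solvent: str) -> int:
    """Number of solvent *beads* filling the volume left by the solute."""
    if n_solute < 0:
        raise ValueError("n_solute must be nonnegative")
    available = box_edge**3 - n_solute * V_ADOH
    if available < 0:
        raise ValueError("solute displaces more than the box volume")
    if solvent == "W":
        rho, mapping = WATER_DENSITY, WATER_MAPPING
    elif solvent == "C":
        rho, mapping = CYCLOHEXANE_DENSITY, CYCLOHEXANE_MAPPING
    else:
        raise ValueError(f"unknown solvent {solvent!r}")
    return int(math.floor(available * rho / mapping + 0.5))


class _Grid:
    """Cell grid for periodic minimum-distance checks during placement."""

    def __init__(self, box_edge: float, min_dist: float):
        self.L = box_edge
        self.m = max(1, int(box_edge / min_dist))
        self.cell = box_edge / self.m
        self.min2 = min_dist * min_dist
        self.cells: Dict[Tuple[int, int, int], List[np.ndarray]] = {}

    def _key(self, p: np.ndarray) -> Tuple[int, int, int]:
        return tuple((p // self.cell).astype(int) % self.m)

    def ok(self, p: np.ndarray) -> bool:
        kx, ky, kz = self._key(p)
        for dx, dy, dz in itertools.product((-1, 0, 1), repeat=3):
            key = ((kx + dx) % self.m, (ky + dy) % self.m, (kz + dz) % self.m)
            for q in self.cells.get(key, ()):
                d = p - q
                d -= self.L * np.round(d / self.L)
                if d @ d < self.min2:
                    return False
        return True

    def add(self, p: np.ndarray) -> None:
        self.cells.setdefault(self._key(p), []).append(p)


def _maxwell_boltzmann(rng, masses: np.ndarray, temperature: float) -> np.ndarray:
    sigma = np.sqrt(KB * temperature / masses)[:, None]
    v = rng.standard_normal((len(masses), 3)) * sigma
    # remove center-of-mass drift
    p_tot = (masses[:, None] * v).sum(axis=0)
    v -= p_tot / masses.sum()
    return v


def build_system(spec: SystemSpec, ff: ForceField, max_retries: int = 2000) -> SystemState:
    """Random sequential insertion of whole molecules, then solvent beads.

    Surfactant chains are grown bond-by-bond at the topology's rest lengths
    in random directions; every inserted bead must keep a minimum distance of
    0.25 nm from all previously placed beads (periodic).  Velocities are
    drawn from the Maxwell-Boltzmann distribution at ``spec.temperature``
    with the total momentum zeroed.
    """
    rng = np.random.default_rng(spec.seed)
    L = spec.box_edge
    n_mol = molecule_count(spec.concentration, L)
    n_solv = solvent_count(L, n_mol, spec.solvent)
    topo = ff.topologies["ADOH"]
    q_mol = ff.topology_charges("ADOH")
    grid = _Grid(L, MIN_PLACEMENT_DIST)

    positions: List[np.ndarray] = []
    species: List[str] = []
    mol_ids: List[int] = []
    mol_names: List[str] = []
    charges: List[float] = []

    bond_r0 = {(i, j): r0 for (i, j, _k, r0) in topo.bonds}

    def random_unit() -> np.ndarray:
        v = rng.standard_normal(3)
        return v / np.linalg.norm(v)

    mol_counter = 0
    for _ in range(n_mol):
        placed = None
        for _attempt in range(max_retries):
            chain = [rng.random(3) * L]
            ok = grid.ok(chain[0])
            for b in range(1, topo.n_beads):
                if not ok:
                    break
                r0 = bond_r0.get((b - 1, b), 0.3)
                for _try in range(30):
                    cand = wrap_positions(chain[-1] + r0 * random_unit(), L)
                    if not grid.ok(cand):
                        continue
                    if len(chain) > 1:
                        d = np.array(chain[:-1]) - cand
                        d -= L * np.round(d / L)
                        if (d * d).sum(axis=1).min() < MIN_PLACEMENT_DIST ** 2:
                            continue
                    chain.append(cand)
                    break
                else:
                    ok = False
            if ok and len(chain) == topo.n_beads:
                placed = chain
                break
        if placed is None:
            frac = len(positions) * MIN_PLACEMENT_DIST**3 / L**3
            raise RuntimeError(
                f"failed to place molecule {mol_counter} after {max_retries} "
                f"retries (packing fraction proxy {frac:.3f})")
        for b, p in enumerate(placed):
            grid.add(p)
            positions.append(p)
            species.append(topo.beads[b])
            mol_ids.append(mol_counter)
            mol_names.append("ADOH")
            charges.append(q_mol[b])
        mol_counter += 1

    solv_name = SOLVENT_NAMES[spec.solvent]
    for _ in range(n_solv):
        for _attempt in range(max_retries):
            cand = rng.random(3) * L
            if grid.ok(cand):
                grid.add(cand)
                positions.append(cand)
                species.append(spec.solvent)
                mol_ids.append(mol_counter)
                mol_names.append(solv_name)
                charges.append(0.0)
                mol_counter += 1
                break
        else:
            frac = len(positions) * MIN_PLACEMENT_DIST**3 / L**3
            raise RuntimeError(
                f"failed to place solvent bead after {max_retries} retries "
                f"(packing fraction proxy {frac:.3f})")

    pos = np.array(positions) if positions else np.zeros((0, 3))
    spc = np.array(species)
    masses = np.array([BEAD_MASSES[s] for s in species]) if species else np.zeros(0)
    vel = (_maxwell_boltzmann(rng, masses, spec.temperature)
           if len(masses) else np.zeros((0, 3)))
    return SystemState(
        box_edge=L, positions=pos, velocities=vel, species=spc,
        molecule_id=np.array(mol_ids, dtype=int), time=0.0, mass=masses,
        charge=np.array(charges), molecule_name=np.array(mol_names),
    )


def _lattice_offsets(n: int) -> np.ndarray:
    """First n points of the integer lattice ordered by distance from origin."""
    r = 1
    while (2 * r + 1) ** 3 < n:
        r += 1
    pts = sorted(itertools.product(range(-r, r + 1), repeat=3),
                 key=lambda p: (p[0] ** 2 + p[1] ** 2 + p[2] ** 2, p))
    return np.array(pts[:n], dtype=float)


def make_planted_clusters(
    sizes: Sequence[int],
    box_edge: float,
    intra_spacing: float = 0.4,
    seed: int = 0,
    bead_spacing: float = 0.1,
    min_gap: float = 4.0,
) -> Tuple[SystemState, Dict]:
    """Surfactant-only configuration with a known cluster partition.

    Each cluster places its molecules on a compact cubic sublattice with
    nearest-neighbor spacing ``intra_spacing`` (so any cutoff above that
    spacing connects them), and cluster centers are spread on a coarse grid
    so that inter-cluster gaps exceed ``min_gap``.  Returns the state and a
    ground-truth dict with per-molecule cluster labels.
    """
    sizes = list(sizes)
    if not sizes or any(s < 1 for s in sizes):
        raise ValueError("sizes must be positive integers")
    rng = np.random.default_rng(seed)
    n_clusters = len(sizes)
    m = max(1, math.ceil(n_clusters ** (1 / 3)))
    pitch = box_edge / m
    # conservative extent of one cluster: lattice radius + molecule extent
    max_size = max(sizes)
    lat_r = max(abs(_lattice_offsets(max_size)).max(), 0.0) * intra_spacing
    extent = lat_r + 2 * bead_spacing + 0.05
    if pitch - 2 * extent <= min_gap:
        raise ValueError(
            f"clusters of extent {extent:.2f} nm on a {pitch:.2f} nm grid "
            f"cannot keep gaps > {min_gap} nm; enlarge the box")

    centers = [np.array([(i + 0.5) * pitch, (j + 0.5) * pitch, (k + 0.5) * pitch])
               for i, j, k in itertools.product(range(m), repeat=3)][:n_clusters]

    beads = ("A", "E", "E", "E", "T")
    bead_off = (np.arange(5) - 2.0)[:, None] * np.array([0.0, 0.0, bead_spacing])

    positions, species, mol_ids, mol_names, labels = [], [], [], [], []
    mol = 0
    for c, (size, center) in enumerate(zip(sizes, centers)):
        offsets = _lattice_offsets(size) * intra_spacing
        jitter = rng.normal(scale=0.01 * intra_spacing, size=(size, 3))
        for k in range(size):
            mol_center = center + offsets[k] + jitter[k]
            for b in range(5):
                positions.append(mol_center + bead_off[b])
                species.append(beads[b])
                mol_ids.append(mol)
                mol_names.append("ADOH")
            labels.append(c)
            mol += 1

    pos = wrap_positions(np.array(positions), box_edge)
    masses = np.array([BEAD_MASSES[s] for s in species])
    state = SystemState(
        box_edge=box_edge, positions=pos, velocities=np.zeros_like(pos),
        species=np.array(species), molecule_id=np.array(mol_ids),
        mass=masses, molecule_name=np.array(mol_names),
    )
    truth = {
        "sizes": sizes,
        "labels": labels,
        "intra_spacing": intra_spacing,
        "min_center_gap": pitch - 2 * extent if n_clusters > 1 else float("inf"),
    }
    return state, truth


def make_brownian_trajectory(
    n_particles: int,
    D: float,
    n_frames: int,
    dt: float,
    box_edge: float,
    seed: int = 0,
) -> Trajectory:
    """Ideal Brownian walkers: Gaussian steps of variance 6*D*dt per frame.

    The returned trajectory carries both wrapped and unwrapped coordinates;
    its ``ground_truth`` records the planted diffusion coefficient.
    """
    if D < 0:
        raise ValueError("D must be nonnegative")
    rng = np.random.default_rng(seed)
    x0 = rng.random((n_particles, 3)) * box_edge
    steps = rng.normal(scale=math.sqrt(2.0 * D * dt),
                       size=(n_frames - 1, n_particles, 3))
    unwrapped = np.concatenate([x0[None], x0[None] + np.cumsum(steps, axis=0)])
    wrapped = wrap_positions(unwrapped, box_edge)
    return Trajectory(
        box_edge=box_edge,
        times=np.arange(n_frames) * dt,
        positions=wrapped,
        unwrapped=unwrapped,
        species=np.array(["TRC"] * n_particles),
        molecule_id=np.arange(n_particles),
        molecule_name=np.array(["TRC"] * n_particles),
        ground_truth={"D": D, "dt": dt},
    )
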