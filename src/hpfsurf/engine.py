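"""Hybrid particle-field molecular dynamics engine.

Instead of pairwise nonbonded potentials, particles interact through
coarse species density fields phi_i(r) evaluated on a cubic mesh by
cloud-in-cell (CIC, trilinear) assignment.  The interaction functional is

    W = sum_cells v_cell / phi0 * [ 1/2 sum_ij chi_ij phi_i phi_j
                                    + kappa_inv/2 (sum_i phi_i - phi0)^2 ]

whose density derivative yields an external potential per species,

    V_i(r) = 1/phi0 * [ sum_j chi_ij phi_j(r) + kappa_inv (phi_tot(r) - phi0) ],

and the force on a particle is the exact negative gradient of the
CIC-discretised energy,

    F_p = - sum_cells V_i(cell) * grad w_cell(x_p),

i.e. the analytic gradient of the trilinear interpolation of V_i.  This
choice makes mesh forces and the discretised energy consistent to machine
precision, which the test suite pins with finite-difference oracles.

Dynamics: velocity Verlet with the density fields (and, optionally, the
spectral Poisson electrostatic potential) recomputed every
``field_update_interval`` steps and frozen in between — the
quasi-instantaneous field approximation.  Temperature is controlled by an
Andersen thermostat: each step every particle's velocity is redrawn from
the Maxwell-Boltzmann distribution with probability nu*dt.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd

from . import _kernels as _k
from .forcefield import ChiMatrix, ForceField
from .system import SystemState, Trajectory, minimum_image, wrap_positions
from .units import KB, KC

__all__ = [
    "SimConfig",
    "DensityField",
    "assign_density",
    "field_potential",
    "interaction_energy",
    "field_forces",
    "bonded_forces",
    "bonded_energy",
    "electrostatic_forces",
    "assign_charges",
    "run",
    "RunResult",
]


@dataclass
class SimConfig:
    """Integrator settings.

    Defaults follow the reference protocol: 30 fs time step, 300 K,
    Andersen collision frequency 7/ps, field update every 20 steps.  The
    default mesh resolution is a cell edge of about 0.5 nm
    (``mesh_cells_per_side=None`` resolves to round(box_edge / 0.5 nm),
    floor 4): comparable to a bead radius, fine enough to resolve the
    intermolecular correlation hole.  A coarser 1 nm mesh lets whole
    molecules overlap inside one cell and piles the center-of-mass RDF up
    at contact instead of producing a first-neighbor peak.
    """

    n_steps: int
    dt: float = 0.03                    # ps
    temperature: float = 300.0          # K
    collision_frequency: float = 7.0    # 1/ps; 0 disables the thermostat
    field_update_interval: int = 20     # steps
    mesh_cells_per_side: Optional[int] = None
    seed: int = 0
    electrostatics_on: bool = False
    frame_stride: int = 100             # steps between emitted frames

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.collision_frequency * self.dt > 1:
            raise ValueError("collision probability nu*dt exceeds 1")
        if self.mesh_cells_per_side is not None and self.mesh_cells_per_side < 4:
            raise ValueError("mesh_cells_per_side must be at least 4")

    def resolve_mesh(self, box_edge: float) -> int:
        if self.mesh_cells_per_side is not None:
            return self.mesh_cells_per_side
        return max(4, int(round(box_edge / 0.5)))


@dataclass
class DensityField:
    """Per-species number densities (and potentials) on a cubic mesh."""

    box_edge: float
    species: Tuple[str, ...]
    phi: np.ndarray                 # (S, M, M, M), nm^-3
    phi0: float                     # nm^-3
    V: Optional[np.ndarray] = None  # (S, M, M, M), kJ/mol

    @property
    def n_cells(self) -> int:
        return self.phi.shape[1]

    @property
    def cell_edge(self) -> float:
        return self.box_edge / self.n_cells

    @property
    def cell_volume(self) -> float:
        return self.cell_edge ** 3


def _cic_indices(pos: np.ndarray, box_edge: float, m: int):
    """Lower/upper cell indices and fractional weights for CIC.

    Density values live at cell centers (cell c is centered at (c+1/2)h).
    """
    h = box_edge / m
    s = pos / h - 0.5
    i0 = np.floor(s).astype(np.int64)
    f = s - i0
    return i0 % m, (i0 + 1) % m, f, h


def _species_indices(labels: np.ndarray, order: Tuple[str, ...]) -> np.ndarray:
    lut = {s: i for i, s in enumerate(order)}
    try:
        return np.array([lut[s] for s in labels], dtype=np.int64)
    except KeyError as e:
        raise ValueError(f"species {e} not present in field/chi ordering") from None


def _cic_scatter(pos, weights_per_particle, sidx, box_edge, m, n_species):
    """Scatter per-particle weights onto an (S, M, M, M) mesh by CIC."""
    flat = _k.scatter(np.ascontiguousarray(pos, dtype=np.float64),
                      np.ascontiguousarray(weights_per_particle, dtype=np.float64),
                      np.ascontiguousarray(sidx, dtype=np.int64),
                      float(box_edge), int(m), int(n_species))
    return flat.reshape(n_species, m, m, m)


def assign_density(state: SystemState, mesh_cells: int,
                   species_order: Optional[Tuple[str, ...]] = None) -> DensityField:
    """Cloud-in-cell number-density assignment.

    The cell sum of phi_i times the cell volume equals the particle count of
    species i to round-off (CIC weights are a partition of unity).
    """
    if species_order is None:
        species_order = tuple(dict.fromkeys(state.species.tolist()))
    sidx = _species_indices(state.species, species_order)
    m = int(mesh_cells)
    mesh = _cic_scatter(state.positions, np.ones(state.n_particles), sidx,
                        state.box_edge, m, len(species_order))
    v_cell = (state.box_edge / m) ** 3
    phi0 = state.n_particles / state.box_edge ** 3
    return DensityField(box_edge=state.box_edge, species=tuple(species_order),
                        phi=mesh / v_cell, phi0=phi0)


def field_potential(field: DensityField, chi: ChiMatrix) -> DensityField:
    """Populate the per-species external potential meshes V_i (kJ/mol)."""
    if tuple(field.species) != tuple(chi.species):
        raise ValueError(
            f"field species {field.species} do not match chi species {chi.species}")
    phi = field.phi
    phi_tot = phi.sum(axis=0)
    V = np.einsum("ij,jxyz->ixyz", chi.values, phi) / field.phi0
    V += (chi.kappa_inv / field.phi0) * (phi_tot - field.phi0)[None]
    field.V = V
    return field


def interaction_energy(field: DensityField, chi: ChiMatrix) -> float:
    """Total density-functional interaction energy W, kJ/mol."""
    if tuple(field.species) != tuple(chi.species):
        raise ValueError("species mismatch between field and chi")
    phi = field.phi
    phi_tot = phi.sum(axis=0)
    pair = 0.5 * np.einsum("ixyz,ij,jxyz->", phi, chi.values, phi)
    comp = 0.5 * chi.kappa_inv * np.sum((phi_tot - field.phi0) ** 2)
    return float(field.cell_volume / field.phi0 * (pair + comp))


def _gather_gradient_force(mesh: np.ndarray, pos: np.ndarray, sidx: np.ndarray,
                           box_edge: float) -> np.ndarray:
    """F = -grad of the trilinear interpolation of ``mesh`` at ``pos``.

    ``mesh`` has shape (S, M, M, M); ``sidx`` selects the per-particle slab.
    """
    m = mesh.shape[1]
    return _k.gather_gradient(np.ascontiguousarray(mesh, dtype=np.float64).ravel(),
                              np.ascontiguousarray(pos, dtype=np.float64),
                              np.ascontiguousarray(sidx, dtype=np.int64),
                              float(box_edge), int(m))


def _cic_gather(mesh: np.ndarray, pos: np.ndarray, sidx: np.ndarray,
                box_edge: float) -> np.ndarray:
    """Trilinear interpolation of an (S, M, M, M) mesh at particle positions."""
    m = mesh.shape[1]
    return _k.gather(np.ascontiguousarray(mesh, dtype=np.float64).ravel(),
                     np.ascontiguousarray(pos, dtype=np.float64),
                     np.ascontiguousarray(sidx, dtype=np.int64),
                     float(box_edge), int(m))


def field_forces(state: SystemState, field: DensityField) -> np.ndarray:
    """Per-particle forces (kJ/mol/nm) from the frozen potential meshes."""
    if field.V is None:
        raise ValueError("field potentials not populated; call field_potential")
    sidx = _species_indices(state.species, field.species)
    return _gather_gradient_force(field.V, state.positions, sidx, state.box_edge)


# ---------------------------------------------------------------------------
# Bonded terms
# ---------------------------------------------------------------------------

def _bond_table(state: SystemState, ff: ForceField):
    """Resolve every molecule against a topology; return bond index arrays."""
    mol_id = state.molecule_id
    order = np.argsort(mol_id, kind="stable")
    sorted_ids = mol_id[order]
    starts = np.searchsorted(sorted_ids, np.unique(sorted_ids))
    counts = np.diff(np.append(starts, len(sorted_ids)))
    by_sequence = {tuple(t.beads): t for t in ff.topologies.values()}
    ai, aj, kb, r0 = [], [], [], []
    for s, c in zip(starts, counts):
        if c == 1:
            continue
        idx = order[s:s + c]
        seq = tuple(state.species[idx])
        topo = by_sequence.get(seq)
        if topo is None:
            raise ValueError(f"no topology matches bead sequence {seq}")
        for (i, j, k, r) in topo.bonds:
            ai.append(idx[i]); aj.append(idx[j]); kb.append(k); r0.append(r)
    return (np.array(ai, dtype=int), np.array(aj, dtype=int),
            np.array(kb, dtype=float), np.array(r0, dtype=float))


def _bonded(state: SystemState, table) -> Tuple[np.ndarray, float]:
    ai, aj, kb, r0 = table
    F = np.zeros_like(state.positions)
    if len(ai) == 0:
        return F, 0.0
    d = minimum_image(state.positions[aj] - state.positions[ai], state.box_edge)
    r = np.linalg.norm(d, axis=1)
    if np.any(r > state.box_edge / 2):
        raise ValueError("bond longer than half the box edge: minimum image ambiguous")
    dr = r - r0
    energy = float(0.5 * np.sum(kb * dr * dr))
    with np.errstate(invalid="ignore", divide="ignore"):
        fmag = np.where(r > 0, kb * dr / r, 0.0)
    fv = fmag[:, None] * d
    np.add.at(F, ai, fv)
    np.add.at(F, aj, -fv)
    return F, energy


def bonded_forces(state: SystemState, ff: ForceField) -> Tuple[np.ndarray, float]:
    """Harmonic bond forces and the total bonded energy (minimum image)."""
    return _bonded(state, _bond_table(state, ff))


def bonded_energy(state: SystemState, ff: ForceField) -> float:
    return bonded_forces(state, ff)[1]


# ---------------------------------------------------------------------------
# Mesh electrostatics (spectral Poisson solve)
# ---------------------------------------------------------------------------

def assign_charges(state: SystemState, ff: ForceField) -> np.ndarray:
    """Per-particle charges resolved from the force-field topologies."""
    if state.charge is not None:
        return state.charge
    mol_id = state.molecule_id
    order = np.argsort(mol_id, kind="stable")
    sorted_ids = mol_id[order]
    starts = np.searchsorted(sorted_ids, np.unique(sorted_ids))
    counts = np.diff(np.append(starts, len(sorted_ids)))
    by_sequence = {tuple(t.beads): t.name for t in ff.topologies.values()}
    q = np.zeros(state.n_particles)
    for s, c in zip(starts, counts):
        idx = order[s:s + c]
        seq = tuple(state.species[idx])
        name = by_sequence.get(seq)
        if name is not None:
            q[idx] = ff.topology_charges(name)
    return q


def _poisson_potential(charges: np.ndarray, pos: np.ndarray, box_edge: float,
                       m: int, epsilon_r: float,
                       deconvolve: bool = False) -> np.ndarray:
    """Electrostatic potential mesh (kJ/mol/e) from CIC-spread charges.

    Periodic spectral solve with the continuum Green's function 4 pi k_C /
    (eps_r k^2); the k=0 mode is zeroed (neutralizing background).  CIC
    window deconvolution is available but off by default: combined with the
    central-difference field gradient it overcorrects, and the plain scheme
    already reproduces the Coulomb far field to ~1%.
    """
    sidx = np.zeros(len(pos), dtype=np.int64)
    rho = _cic_scatter(pos, charges, sidx, box_edge, m, 1)[0]
    h = box_edge / m
    rho /= h ** 3                      # e / nm^3
    rho_k = np.fft.rfftn(rho)
    kx = 2 * np.pi * np.fft.fftfreq(m, d=h)
    kz = 2 * np.pi * np.fft.rfftfreq(m, d=h)
    KX, KY, KZ = np.meshgrid(kx, kx, kz, indexing="ij")
    k2 = KX ** 2 + KY ** 2 + KZ ** 2
    k2[0, 0, 0] = np.inf
    green = 4 * np.pi * KC / (epsilon_r * k2)
    if deconvolve:
        wx = np.sinc(kx * h / (2 * np.pi)) ** 2
        wz = np.sinc(kz * h / (2 * np.pi)) ** 2
        W = wx[:, None, None] * wx[None, :, None] * wz[None, None, :]
        green = green / W ** 2
    psi = np.fft.irfftn(rho_k * green, s=(m, m, m), axes=(0, 1, 2))
    return psi


def _electric_field_mesh(psi: np.ndarray, h: float) -> np.ndarray:
    """E = -grad psi by periodic central differences on the mesh.

    Using an antisymmetric difference with the same CIC window for both
    charge spreading and field interpolation makes the self-force of each
    particle on itself vanish identically (the classic particle-mesh
    momentum-conserving scheme).
    """
    E = np.empty((3,) + psi.shape)
    for d in range(3):
        E[d] = -(np.roll(psi, -1, axis=d) - np.roll(psi, 1, axis=d)) / (2 * h)
    return E


def _electrostatic_force_from_mesh(E: np.ndarray, pos: np.ndarray,
                                   q: np.ndarray, box_edge: float) -> np.ndarray:
    zero = np.zeros(len(pos), dtype=np.int64)
    F = np.empty_like(pos)
    for d in range(3):
        F[:, d] = _cic_gather(E[d][None], pos, zero, box_edge) * q
    return F


def electrostatic_forces(state: SystemState, ff: ForceField,
                         mesh_cells: int) -> np.ndarray:
    """Mesh electrostatic forces (kJ/mol/nm) on all particles.

    Requires an overall neutral system (the periodic Poisson problem is
    otherwise ill-posed beyond a uniform background).
    """
    q = assign_charges(state, ff)
    if abs(q.sum()) > 1e-9:
        raise ValueError(f"system net charge {q.sum():.3g} e is not zero")
    if not np.any(q):
        return np.zeros_like(state.positions)
    psi = _poisson_potential(q, state.positions, state.box_edge, mesh_cells,
                             ff.epsilon_r)
    E = _electric_field_mesh(psi, state.box_edge / mesh_cells)
    return _electrostatic_force_from_mesh(E, state.positions, q, state.box_edge)


# ---------------------------------------------------------------------------
# Time integration
# ---------------------------------------------------------------------------

@dataclass
class RunResult:
    trajectory: Trajectory
    log: pd.DataFrame           # step, time, kinetic_T, field_W, bonded_E
    manifest: dict


def _kinetic_temperature(vel: np.ndarray, mass: np.ndarray) -> float:
    ke = 0.5 * float(np.sum(mass[:, None] * vel ** 2))
    return 2.0 * ke / (3.0 * len(mass) * KB)


def run(state: SystemState, ff: ForceField, cfg: SimConfig) -> RunResult:
    """NVT velocity-Verlet run under the quasi-instantaneous field approximation.

    Returns the trajectory (wrapped + unwrapped coordinates), a run log
    sampled at the frame stride, and a manifest echoing the configuration.
    """
    rng = np.random.default_rng(cfg.seed)
    st = state.copy()
    n = st.n_particles
    if st.mass is None:
        raise ValueError("state must carry per-particle masses")
    mass = st.mass
    m_cells = cfg.resolve_mesh(st.box_edge)
    species_order = tuple(ff.chi.species)
    sidx = _species_indices(st.species, species_order)
    table = _bond_table(st, ff)
    charges = assign_charges(st, ff) if cfg.electrostatics_on else None
    if charges is not None and abs(charges.sum()) > 1e-9:
        raise ValueError("electrostatics requires a neutral system")

    unwrapped = st.positions.copy()
    inv_mass = 1.0 / mass[:, None]
    sigma_v = np.sqrt(KB * cfg.temperature / mass)
    p_coll = cfg.collision_frequency * cfg.dt

    def update_fields():
        fld = assign_density(st, m_cells, species_order)
        field_potential(fld, ff.chi)
        E = None
        if charges is not None and np.any(charges):
            psi = _poisson_potential(charges, st.positions, st.box_edge,
                                     m_cells, ff.epsilon_r)
            E = _electric_field_mesh(psi, st.box_edge / m_cells)
        return fld, E

    def forces(fld, E):
        F = _gather_gradient_force(fld.V, st.positions, sidx, st.box_edge)
        Fb, Eb = _bonded(st, table)
        F += Fb
        if E is not None:
            F += _electrostatic_force_from_mesh(E, st.positions, charges,
                                                st.box_edge)
        return F, Eb

    fld, Emesh = update_fields()
    F, Eb = forces(fld, Emesh)

    frames_w: List[np.ndarray] = [st.positions.copy()]
    frames_u: List[np.ndarray] = [unwrapped.copy()]
    times: List[float] = [st.time]
    log_rows = [(0, st.time, _kinetic_temperature(st.velocities, mass),
                 interaction_energy(fld, ff.chi), Eb)]

    for step in range(1, cfg.n_steps + 1):
        st.velocities += 0.5 * cfg.dt * F * inv_mass
        disp = cfg.dt * st.velocities
        unwrapped += disp
        st.positions = wrap_positions(st.positions + disp, st.box_edge)
        if step % cfg.field_update_interval == 0:
            fld, Emesh = update_fields()
        F, Eb = forces(fld, Emesh)
        if not np.all(np.isfinite(F)):
            bad = np.where(~np.isfinite(F).all(axis=1))[0][:5]
            raise FloatingPointError(
                f"non-finite force at step {step}, particles {bad.tolist()}")
        st.velocities += 0.5 * cfg.dt * F * inv_mass
        if p_coll > 0:
            hit = rng.random(n) < p_coll
            k = int(hit.sum())
            if k:
                st.velocities[hit] = (rng.standard_normal((k, 3))
                                      * sigma_v[hit, None])
        st.time += cfg.dt
        if step % cfg.frame_stride == 0:
            frames_w.append(st.positions.copy())
            frames_u.append(unwrapped.copy())
            times.append(st.time)
            log_rows.append((step, st.time,
                             _kinetic_temperature(st.velocities, mass),
                             interaction_energy(
                                 field_potential(assign_density(
                                     st, m_cells, species_order), ff.chi),
                                 ff.chi),
                             Eb))

    traj = Trajectory(
        box_edge=st.box_edge, times=np.array(times),
        positions=np.array(frames_w), unwrapped=np.array(frames_u),
        species=st.species.copy(), molecule_id=st.molecule_id.copy(),
        mass=mass.copy(),
        molecule_name=(None if st.molecule_name is None
                       else st.molecule_name.copy()),
    )
    log = pd.DataFrame(log_rows, columns=["step", "time", "kinetic_T",
                                          "field_W", "bonded_E"])
    manifest = {
        "n_particles": n,
        "n_steps": cfg.n_steps,
        "dt_ps": cfg.dt,
        "temperature_K": cfg.temperature,
        "collision_frequency_per_ps": cfg.collision_frequency,
        "field_update_interval": cfg.field_update_interval,
        "mesh_cells_per_side": m_cells,
        "seed": cfg.seed,
        "electrostatics_on": cfg.electrostatics_on,
        "frame_stride": cfg.frame_stride,
    }
    return RunResult(trajectory=traj, log=log, manifest=manifest)
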