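"""Structural and dynamic observables on configurations and trajectories.

* Cluster analysis: two surfactant molecules belong to the same aggregate
  when any inter-molecular bead pair lies within a cutoff (minimum image);
  aggregates are the connected components of that contact graph.  The
  cutoff defaults to 0.8 nm, just past the ~0.75 nm first maximum of the
  surfactant-surfactant center-of-mass RDF, and is exposed everywhere
  because cluster statistics are cutoff sensitive.
* Radial distribution functions with a small selection grammar
  (``"species=A"``, ``"molecule=ADOH and com"``).
* Mean-square displacement with multiple time origins and the Einstein
  relation fit sigma^2(t) = 6 D t + A.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .system import SystemState, Trajectory, minimum_image
from .units import D_TO_1E5_CM2_S

__all__ = [
    "ClusterReport",
    "RDFResult",
    "MSDResult",
    "DiffusionFit",
    "find_clusters",
    "aggregate_cluster_series",
    "radial_distribution",
    "mean_square_displacement",
    "fit_diffusion",
]

DEFAULT_CLUSTER_CUTOFF = 0.8  # nm
SOLVENT_SPECIES = frozenset({"C", "W"})


@dataclass
class ClusterReport:
    """Cluster census of the surfactant molecules in one frame."""

    time: float
    molecule_ids: np.ndarray       # global ids of the surfactant molecules
    labels: np.ndarray             # cluster label per surfactant molecule
    histogram: Dict[int, int]      # aggregate size -> number of aggregates
    mean_size: float
    monomer_fraction: float

    @property
    def n_molecules(self) -> int:
        return len(self.molecule_ids)


def _surfactant_molecules(state: SystemState,
                          solvent_species=SOLVENT_SPECIES) -> np.ndarray:
    """Boolean mask over particles belonging to surfactant molecules."""
    mask = np.array([s not in solvent_species for s in state.species])
    surf_ids = np.unique(state.molecule_id[mask])
    return np.isin(state.molecule_id, surf_ids)


def find_clusters(state: SystemState, cutoff: float = DEFAULT_CLUSTER_CUTOFF,
                  solvent_species=SOLVENT_SPECIES) -> ClusterReport:
    """Connected-component aggregates from inter-molecular bead contacts.

    Cluster labels are deterministic: each cluster is labelled by the
    smallest molecule id it contains.
    """
    if cutoff <= 0 or cutoff >= state.box_edge / 2:
        raise ValueError("cutoff must lie in (0, box_edge/2)")
    mask = _surfactant_molecules(state, solvent_species)
    if not mask.any():
        raise ValueError("no surfactant molecules in state")
    pos = np.mod(state.positions[mask], state.box_edge)
    mol = state.molecule_id[mask]
    mol_ids = np.unique(mol)
    mol_index = np.searchsorted(mol_ids, mol)
    n_mol = len(mol_ids)

    tree = cKDTree(pos, boxsize=state.box_edge)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    if len(pairs):
        mi, mj = mol_index[pairs[:, 0]], mol_index[pairs[:, 1]]
        keep = mi != mj
        adj = coo_matrix((np.ones(keep.sum()), (mi[keep], mj[keep])),
                         shape=(n_mol, n_mol))
        _, comp = connected_components(adj, directed=False)
    else:
        comp = np.arange(n_mol)

    # relabel components by their smallest member molecule id
    labels = np.empty(n_mol, dtype=int)
    for c in np.unique(comp):
        members = comp == c
        labels[members] = mol_ids[members].min()

    sizes = np.bincount(np.searchsorted(np.unique(labels), labels))
    histogram: Dict[int, int] = {}
    for s in sizes:
        histogram[int(s)] = histogram.get(int(s), 0) + 1
    mean_size = float(sizes.mean())
    monomer_fraction = float((sizes == 1).sum() / n_mol)
    return ClusterReport(time=state.time, molecule_ids=mol_ids, labels=labels,
                         histogram=histogram, mean_size=mean_size,
                         monomer_fraction=monomer_fraction)


def aggregate_cluster_series(
    reports: Sequence[ClusterReport], bin_width: int = 1
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Per-frame cluster statistics plus the pooled size distribution.

    Returns ``(series, pooled)``: a frame-by-frame table of mean size and
    monomer fraction, and the pooled normalized aggregate-size distribution
    binned with ``bin_width`` (a width of 5 reproduces the coarse
    presentation used for polydisperse micelles).
    """
    if not reports:
        raise ValueError("empty report list")
    series = pd.DataFrame({
        "time": [r.time for r in reports],
        "mean_size": [r.mean_size for r in reports],
        "monomer_fraction": [r.monomer_fraction for r in reports],
    })
    pooled: Dict[int, int] = {}
    for r in reports:
        for size, count in r.histogram.items():
            pooled[size] = pooled.get(size, 0) + count
    max_size = max(pooled)
    edges = np.arange(1, max_size + bin_width + 1, bin_width)
    counts = np.zeros(len(edges) - 1)
    for size, count in pooled.items():
        counts[np.searchsorted(edges, size, side="right") - 1] += count
    prob = counts / counts.sum()
    pooled_df = pd.DataFrame({
        "size_min": edges[:-1],
        "size_max": edges[1:] - 1,
        "probability": prob,
    })
    return series, pooled_df


# ---------------------------------------------------------------------------
# Selections
# ---------------------------------------------------------------------------

def _parse_selection(expr: str) -> dict:
    out = {"species": None, "molecule": None, "com": False}
    for tok in expr.replace(";", " ").split():
        if tok.lower() == "and":
            continue
        if tok.lower() == "com":
            out["com"] = True
        elif "=" in tok:
            key, val = tok.split("=", 1)
            if key not in ("species", "molecule"):
                raise ValueError(f"unknown selection key {key!r}")
            out[key] = val
        else:
            raise ValueError(f"cannot parse selection token {tok!r}")
    return out


class _Selection:
    """Resolved selection: bead indices, or per-molecule COM groups."""

    def __init__(self, traj: Trajectory, expr: str):
        sel = _parse_selection(expr)
        mask = np.ones(traj.n_particles, dtype=bool)
        if sel["species"] is not None:
            mask &= traj.species == sel["species"]
        if sel["molecule"] is not None:
            if traj.molecule_name is None:
                raise ValueError("trajectory carries no molecule names")
            mask &= traj.molecule_name == sel["molecule"]
        if not mask.any():
            raise ValueError(f"selection {expr!r} matches nothing")
        self.expr = expr
        self.com = sel["com"]
        self.indices = np.where(mask)[0]
        if self.com:
            mol = traj.molecule_id[self.indices]
            self.groups = [self.indices[mol == m] for m in np.unique(mol)]
            w = traj.mass if traj.mass is not None else np.ones(traj.n_particles)
            self.weights = [w[g] / w[g].sum() for g in self.groups]

    def n_centers(self) -> int:
        return len(self.groups) if self.com else len(self.indices)

    def positions(self, frame_pos: np.ndarray, box_edge: float) -> np.ndarray:
        if not self.com:
            return frame_pos[self.indices]
        out = np.empty((len(self.groups), 3))
        for k, (g, w) in enumerate(zip(self.groups, self.weights)):
            p = frame_pos[g]
            # unwrap the molecule around its first bead before averaging
            rel = minimum_image(p - p[0], box_edge)
            out[k] = p[0] + w @ rel
        return np.mod(out, box_edge)


@dataclass
class RDFResult:
    r: np.ndarray                  # bin centers, nm
    g: np.ndarray                  # dimensionless
    selection_a: str
    selection_b: str
    n_frames: int

    def first_maximum(self) -> float:
        """Bin center of the global maximum of g(r)."""
        return float(self.r[np.argmax(self.g)])


def radial_distribution(
    traj: Trajectory,
    selection_a: str,
    selection_b: str,
    r_max: float,
    bin_width: float = 0.05,
    frames: Optional[slice] = None,
) -> RDFResult:
    """Pair correlation function averaged over frames.

    Counts are normalized by the ideal-gas expectation
    N_A * rho_B * 4 pi r^2 dr per frame; for identical selections self
    pairs are excluded.
    """
    if r_max > traj.box_edge / 2:
        raise ValueError("r_max must not exceed half the box edge")
    sel_a = _Selection(traj, selection_a)
    sel_b = _Selection(traj, selection_b)
    same = (selection_a == selection_b)
    edges = np.arange(0.0, r_max + bin_width, bin_width)
    counts = np.zeros(len(edges) - 1)
    frame_idx = range(traj.n_frames)[frames] if frames is not None \
        else range(traj.n_frames)
    n_frames = 0
    for fi in frame_idx:
        pos = np.mod(traj.positions[fi], traj.box_edge)
        pa = sel_a.positions(pos, traj.box_edge)
        if same:
            pb = pa
            tree = cKDTree(pa, boxsize=traj.box_edge)
            # element 0 of the non-cumulative counts holds d <= edges[0] = 0,
            # i.e. exactly the self pairs; dropping it excludes them
            c = tree.count_neighbors(tree, edges, cumulative=False)[1:]
        else:
            pb = sel_b.positions(pos, traj.box_edge)
            tree_a = cKDTree(pa, boxsize=traj.box_edge)
            tree_b = cKDTree(pb, boxsize=traj.box_edge)
            c = tree_a.count_neighbors(tree_b, edges, cumulative=False)[1:]
        counts += c
        n_frames += 1
    n_a = sel_a.n_centers()
    n_b = sel_b.n_centers() - (1 if same else 0)
    volume = traj.box_edge ** 3
    shell = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    ideal = n_a * (n_b / volume) * shell * n_frames
    with np.errstate(invalid="ignore", divide="ignore"):
        g = np.where(ideal > 0, counts / ideal, 0.0)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return RDFResult(r=centers, g=g, selection_a=selection_a,
                     selection_b=selection_b, n_frames=n_frames)


# ---------------------------------------------------------------------------
# Mean-square displacement and the Einstein relation
# ---------------------------------------------------------------------------

@dataclass
class MSDResult:
    lags: np.ndarray               # ps
    msd: np.ndarray                # nm^2
    n_particles: int


@dataclass
class DiffusionFit:
    D: float                       # nm^2/ps
    A: float                       # nm^2 (intercept)
    r_squared: float
    alpha: float                   # log-log slope over the fit window
    window: Tuple[float, float]    # ps

    @property
    def D_1e5_cm2_s(self) -> float:
        """Diffusion coefficient in 10^-5 cm^2/s."""
        return self.D * D_TO_1E5_CM2_S

    @property
    def is_diffusive(self) -> bool:
        """True when the MSD grows ~linearly over the fit window."""
        return bool(abs(self.alpha - 1.0) < 0.25)


def mean_square_displacement(traj: Trajectory,
                             selection: Optional[str] = None) -> MSDResult:
    """sigma^2(t) averaged over particles and multiple time origins.

    Origins are spaced by half the lag (50% overlap), which trades the
    variance reduction of dense origins against their correlation.
    Requires unwrapped coordinates (engine trajectories carry them
    natively; imported wrapped trajectories are unwrapped by minimum-image
    displacement chaining at load time).
    """
    u = traj.unwrapped
    if selection is not None:
        sel = _Selection(traj, selection)
        if sel.com:
            raise ValueError("MSD selections operate on beads, not COMs")
        u = u[:, sel.indices]
    n_frames = len(u)
    lags = np.arange(n_frames)
    msd = np.zeros(n_frames)
    for lag in lags[1:]:
        stride = max(1, lag // 2)
        origins = np.arange(0, n_frames - lag, stride)
        d = u[origins + lag] - u[origins]
        msd[lag] = np.mean(np.sum(d * d, axis=-1))
    dt = float(traj.times[1] - traj.times[0]) if n_frames > 1 else 0.0
    return MSDResult(lags=lags * dt, msd=msd, n_particles=u.shape[1])


def fit_diffusion(msd: MSDResult,
                  window: Optional[Tuple[float, float]] = None) -> DiffusionFit:
    """Least-squares Einstein-relation fit sigma^2(t) = 6 D t + A.

    The default window spans 10-50% of the maximum lag, skipping the
    short-time regime and the poorly averaged long-lag tail.
    """
    t_max = msd.lags.max()
    if window is None:
        window = (0.1 * t_max, 0.5 * t_max)
    lo, hi = window
    mask = (msd.lags >= lo) & (msd.lags <= hi)
    if mask.sum() < 2:
        raise ValueError(f"fit window {window} contains fewer than 2 lags")
    t, y = msd.lags[mask], msd.msd[mask]
    slope, intercept = np.polyfit(t, y, 1)
    pred = slope * t + intercept
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    pos = (t > 0) & (y > 0)
    if pos.sum() >= 2:
        alpha = float(np.polyfit(np.log(t[pos]), np.log(y[pos]), 1)[0])
    else:
        alpha = float("nan")
    return DiffusionFit(D=float(slope / 6.0), A=float(intercept),
                        r_squared=r2, alpha=alpha, window=(float(lo), float(hi)))
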