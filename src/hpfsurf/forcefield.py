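"""Coarse-grained chemical model of the ADOH surfactant and its solvents.

The surfactant (an adamantyl head linked to a triethylene-glycol tail capped
by a hydroxyl group) is mapped onto a linear five-bead chain A-E-E-E-T:

* ``A`` -- the adamantyl head group (C10H15),
* ``E`` -- one ethylene-oxide repeat of the TEG tail (CH2CH2O),
* ``T`` -- the terminal hydroxyl,
* ``C`` -- one cyclohexane molecule (single-bead solvent),
* ``W`` -- four water molecules lumped into one bead.

Nonbonded chemistry lives entirely in the Flory-Huggins-like interaction
matrix chi_ij (kJ/mol) used by the density-field Hamiltonian, plus a
compressibility penalty 1/kappa that punishes deviations of the total bead
density from its homogeneous reference value.  For cyclohexane systems the
tail beads optionally carry small alternating partial charges (+0.4/-0.4 e)
screened by a relative dielectric constant eps_r = 5, mimicking the
quadrupolar character of the glycol-ether segment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Tuple

import numpy as np

__all__ = [
    "BeadSpec",
    "ChiMatrix",
    "MoleculeTopology",
    "ForceField",
    "default_adoh_forcefield",
    "validate_forcefield",
    "dump_forcefield",
    "load_forcefield",
]

#: Masses of the mapped atom groups, amu.
BEAD_MASSES = {
    "A": 135.2,   # adamantyl C10H15
    "E": 44.05,   # CH2CH2O repeat
    "T": 17.01,   # OH
    "C": 84.16,   # cyclohexane
    "W": 72.06,   # four H2O
}

BEAD_NOTES = {
    "A": "adamantyl head, C10H15",
    "E": "one TEG repeat, CH2CH2O",
    "T": "terminal hydroxyl, OH",
    "C": "one cyclohexane molecule",
    "W": "four water molecules",
}

#: Off-diagonal interaction parameters chi_ij, kJ/mol.
CHI_VALUES = {
    ("A", "E"): 7.8,
    ("A", "T"): 13.25,
    ("A", "C"): 0.0,
    ("A", "W"): 33.75,
    ("E", "T"): 4.5,
    ("E", "C"): 7.8,
    ("E", "W"): 1.5,
    ("T", "C"): 13.25,
    ("T", "W"): 0.0,
}

#: Default compressibility prefactor 1/kappa, kJ/mol.
DEFAULT_KAPPA_INV = 5.0

#: Default harmonic bond parameters (k_b kJ/mol/nm^2, r0 nm).
BOND_AE = (1250.0, 0.33)
BOND_EE = (1250.0, 0.28)
BOND_ET = (1250.0, 0.28)

#: Alternating partial charges on the tail beads E1 E2 E3 T (elementary charge).
TAIL_CHARGES = (0.4, -0.4, 0.4, -0.4)


@dataclass(frozen=True)
class BeadSpec:
    """One coarse-grained bead species."""

    name: str
    mass: float
    charge: float = 0.0
    mapping_note: str = ""

    def __post_init__(self) -> None:
        if self.mass <= 0:
            raise ValueError(f"bead {self.name!r}: mass must be positive")


@dataclass
class ChiMatrix:
    """Symmetric zero-diagonal interaction matrix plus compressibility term."""

    species: Tuple[str, ...]
    values: np.ndarray            # (S, S), kJ/mol
    kappa_inv: float = DEFAULT_KAPPA_INV

    def __post_init__(self) -> None:
        self.species = tuple(self.species)
        self.values = np.asarray(self.values, dtype=float)
        s = len(self.species)
        if self.values.shape != (s, s):
            raise ValueError("chi matrix shape does not match species list")

    def index(self, label: str) -> int:
        try:
            return self.species.index(label)
        except ValueError:
            raise KeyError(f"unknown species {label!r}") from None

    def chi(self, a: str, b: str) -> float:
        return float(self.values[self.index(a), self.index(b)])

    def violations(self) -> List[str]:
        out = []
        for i, a in enumerate(self.species):
            for j, b in enumerate(self.species):
                if j <= i:
                    continue
                if self.values[i, j] != self.values[j, i]:
                    out.append(f"asymmetric pair ({a},{b})")
        if np.any(np.diagonal(self.values) != 0.0):
            out.append("nonzero diagonal chi")
        if self.kappa_inv < 0:
            out.append("negative kappa_inv")
        return out


@dataclass
class MoleculeTopology:
    """Bead sequence and harmonic bonded terms of one molecule type.

    ``bonds`` is a list of (i, j, k_b, r0); ``angles`` an optional list of
    (i, j, k, k_a, theta0) harmonic angle terms (none by default: the tail is
    deliberately a fully flexible chain).
    """

    name: str
    beads: Tuple[str, ...]
    bonds: List[Tuple[int, int, float, float]] = field(default_factory=list)
    angles: List[Tuple[int, int, int, float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.beads = tuple(self.beads)
        n = len(self.beads)
        for i, j, *_ in self.bonds:
            if i == j:
                raise ValueError(f"topology {self.name!r}: self-bond ({i},{i})")
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"topology {self.name!r}: bond index out of range")

    @property
    def n_beads(self) -> int:
        return len(self.beads)


@dataclass
class ForceField:
    """Complete coarse-grained model: beads, chi matrix, topologies, charges."""

    beads: List[BeadSpec]
    chi: ChiMatrix
    topologies: Dict[str, MoleculeTopology]
    epsilon_r: float = 1.0
    tail_charges_enabled: bool = False
    #: per-topology, per-bead charges (e); empty tuple means all zero
    charges: Dict[str, Tuple[float, ...]] = field(default_factory=dict)

    def bead(self, name: str) -> BeadSpec:
        for b in self.beads:
            if b.name == name:
                return b
        raise KeyError(f"unknown bead {name!r}")

    def mass_of(self, name: str) -> float:
        return self.bead(name).mass

    def topology_charges(self, name: str) -> Tuple[float, ...]:
        topo = self.topologies[name]
        q = self.charges.get(name)
        if q is None:
            return (0.0,) * topo.n_beads
        return q


def _adoh_topology() -> MoleculeTopology:
    return MoleculeTopology(
        name="ADOH",
        beads=("A", "E", "E", "E", "T"),
        bonds=[
            (0, 1, *BOND_AE),
            (1, 2, *BOND_EE),
            (2, 3, *BOND_EE),
            (3, 4, *BOND_ET),
        ],
    )


def default_adoh_forcefield(solvent: str = "W", charged_tails: bool = False) -> ForceField:
    """The reference parameterization for ADOH in water or cyclohexane.

    Parameters
    ----------
    solvent
        ``"W"`` (water, 4:1 mapped) or ``"C"`` (cyclohexane, 1:1 mapped).
    charged_tails
        Place alternating +-0.4 e charges on the four tail beads (the ADOH
        molecule stays neutral) and set eps_r = 5.  Meant for cyclohexane
        systems, where weak electrostatics drives the residual clustering.
    """
    if solvent not in ("W", "C"):
        raise ValueError(f"unknown solvent label {solvent!r}; expected 'W' or 'C'")
    species = ("A", "E", "T", solvent)
    s = len(species)
    values = np.zeros((s, s))
    for (a, b), v in CHI_VALUES.items():
        if a in species and b in species:
            i, j = species.index(a), species.index(b)
            values[i, j] = values[j, i] = v
    chi = ChiMatrix(species=species, values=values, kappa_inv=DEFAULT_KAPPA_INV)
    solvent_topo = MoleculeTopology(name={"W": "SOL", "C": "CHX"}[solvent],
                                    beads=(solvent,))
    topo = _adoh_topology()
    beads = [BeadSpec(name=s_, mass=BEAD_MASSES[s_], mapping_note=BEAD_NOTES[s_])
             for s_ in species]
    ff = ForceField(
        beads=beads,
        chi=chi,
        topologies={topo.name: topo, solvent_topo.name: solvent_topo},
        epsilon_r=5.0 if charged_tails else 1.0,
        tail_charges_enabled=charged_tails,
    )
    if charged_tails:
        ff.charges["ADOH"] = (0.0,) + TAIL_CHARGES
    return ff


def validate_forcefield(ff: ForceField) -> List[str]:
    """Collect invariant violations; an empty list means the model is valid."""
    out = list(ff.chi.violations())
    names = [b.name for b in ff.beads]
    if len(set(names)) != len(names):
        out.append("duplicate bead names")
    for topo in ff.topologies.values():
        for s in topo.beads:
            if s not in names:
                out.append(f"topology {topo.name!r} uses unknown species {s!r}")
    if ff.tail_charges_enabled:
        for name, q in ff.charges.items():
            if abs(sum(q)) > 1e-12:
                out.append("nonzero molecular charge")
    return out


# ---------------------------------------------------------------------------
# Plain-text serialization.  Floats are written with repr so that a
# dump -> load round trip reproduces every chi value bit-exactly.
# ---------------------------------------------------------------------------

def dump_forcefield(ff: ForceField) -> str:
    lines = ["[options]",
             f"epsilon_r = {ff.epsilon_r!r}",
             f"tail_charges_enabled = {ff.tail_charges_enabled}",
             "", "[beads]"]
    for b in ff.beads:
        lines.append(f"{b.name} mass={b.mass!r} charge={b.charge!r} note={b.mapping_note}")
    lines += ["", "[chi]",
              "species = " + " ".join(ff.chi.species),
              f"kappa_inv = {ff.chi.kappa_inv!r}"]
    for i, a in enumerate(ff.chi.species):
        for j, b in enumerate(ff.chi.species):
            if j > i:
                lines.append(f"{a} {b} {float(ff.chi.values[i, j])!r}")
    for topo in ff.topologies.values():
        lines += ["", f"[topology {topo.name}]",
                  "beads = " + " ".join(topo.beads)]
        for (i, j, k, r0) in topo.bonds:
            lines.append(f"bond {i} {j} {k!r} {r0!r}")
        for (i, j, k, ka, th0) in topo.angles:
            lines.append(f"angle {i} {j} {k} {ka!r} {th0!r}")
        q = ff.charges.get(topo.name)
        if q is not None:
            lines.append("charges = " + " ".join(repr(x) for x in q))
    return "\n".join(lines) + "\n"


def load_forcefield(text: str) -> ForceField:
    section = None
    topo_name = None
    options: Dict[str, str] = {}
    beads: List[BeadSpec] = []
    chi_species: Tuple[str, ...] = ()
    kappa_inv = DEFAULT_KAPPA_INV
    chi_entries: Dict[Tuple[str, str], float] = {}
    topologies: Dict[str, MoleculeTopology] = {}
    charges: Dict[str, Tuple[float, ...]] = {}

    for raw in text.splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith("["):
            header = line.strip("[]").strip()
            if header.startswith("topology"):
                section = "topology"
                topo_name = header.split(None, 1)[1]
                topologies[topo_name] = MoleculeTopology(name=topo_name, beads=())
            else:
                section = header
            continue
        if section == "options":
            key, val = (x.strip() for x in line.split("=", 1))
            options[key] = val
        elif section == "beads":
            name, rest = line.split(None, 1)
            kv = dict(item.split("=", 1) for item in rest.split(" ") if "=" in item)
            note = rest.split("note=", 1)[1] if "note=" in rest else ""
            beads.append(BeadSpec(name=name, mass=float(kv["mass"]),
                                  charge=float(kv["charge"]), mapping_note=note))
        elif section == "chi":
            if line.startswith("species"):
                chi_species = tuple(line.split("=", 1)[1].split())
            elif line.startswith("kappa_inv"):
                kappa_inv = float(line.split("=", 1)[1])
            else:
                a, b, v = line.split()
                chi_entries[(a, b)] = float(v)
        elif section == "topology":
            topo = topologies[topo_name]
            if line.startswith("beads"):
                topo.beads = tuple(line.split("=", 1)[1].split())
            elif line.startswith("bond "):
                _, i, j, k, r0 = line.split()
                topo.bonds.append((int(i), int(j), float(k), float(r0)))
            elif line.startswith("angle "):
                _, i, j, k, ka, th0 = line.split()
                topo.angles.append((int(i), int(j), int(k), float(ka), float(th0)))
            elif line.startswith("charges"):
                charges[topo_name] = tuple(
                    float(x) for x in line.split("=", 1)[1].split())
        else:
            raise ValueError(f"line outside any section: {raw!r}")

    s = len(chi_species)
    values = np.zeros((s, s))
    for (a, b), v in chi_entries.items():
        i, j = chi_species.index(a), chi_species.index(b)
        values[i, j] = values[j, i] = v
    return ForceField(
        beads=beads,
        chi=ChiMatrix(species=chi_species, values=values, kappa_inv=kappa_inv),
        topologies=topologies,
        epsilon_r=float(options.get("epsilon_r", 1.0)),
        tail_charges_enabled=options.get("tail_charges_enabled", "False") == "True",
        charges=charges,
    )
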