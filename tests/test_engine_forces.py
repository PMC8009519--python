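"""Force correctness: finite-difference and analytic oracles.

The mesh force must be the exact negative gradient of the discretised
interaction energy (density reassigned at the displaced position), bonded
forces must match Hooke's law and their own finite-difference oracle, and
the spectral Poisson solver must reproduce the Coulomb far field.
"""

import numpy as np
import pytest

from hpfsurf.engine import (assign_density, bonded_forces,
                            electrostatic_forces, field_forces,
                            field_potential, interaction_energy)
from hpfsurf.forcefield import default_adoh_forcefield
from hpfsurf.system import SystemState
from hpfsurf.units import KC


def make_state(positions, species, box=5.0, mol_id=None, charge=None):
    positions = np.asarray(positions, dtype=float)
    n = len(positions)
    return SystemState(
        box_edge=box, positions=positions, velocities=np.zeros((n, 3)),
        species=np.asarray(species),
        molecule_id=np.arange(n) if mol_id is None else np.asarray(mol_id),
        mass=np.ones(n), charge=charge)


class TestFieldForces:
    def test_uniform_potential_zero_force(self):
        rng = np.random.default_rng(0)
        st = make_state(rng.random((20, 3)) * 5.0, ["W"] * 20)
        fld = assign_density(st, 5, ("W",))
        fld.V = np.full((1, 5, 5, 5), 3.7)
        F = field_forces(st, fld)
        assert np.allclose(F, 0.0, atol=1e-12)

    def test_linear_ramp_constant_force(self):
        """V increasing along x at slope s pushes particles with force -s."""
        st = make_state([[2.25, 1.3, 3.7], [0.75, 4.1, 0.2]], ["W", "W"], box=5.0)
        fld = assign_density(st, 5, ("W",))
        h = 1.0
        ramp = np.arange(5) * h * 2.0       # slope 2 kJ/mol/nm along x
        fld.V = np.broadcast_to(ramp[None, :, None, None], (1, 5, 5, 5)).copy()
        F = field_forces(st, fld)
        # particles sit at cell centers in x, away from the periodic seam
        assert np.allclose(F[:, 0], -2.0)
        assert np.allclose(F[:, 1:], 0.0, atol=1e-12)

    def test_forces_equal_finite_difference_gradient_of_energy(self):
        """Central finite differences of W (with density reassignment) match
        the analytic mesh force to 1e-4 relative."""
        rng = np.random.default_rng(42)
        n = 30
        box, m = 5.0, 5
        species = rng.choice(["A", "E", "T", "W"], size=n)
        pos = rng.random((n, 3)) * box
        ff = default_adoh_forcefield("W")
        order = tuple(ff.chi.species)
        st = make_state(pos, species, box=box)
        fld = field_potential(assign_density(st, m, order), ff.chi)
        F = field_forces(st, fld)

        def energy(p):
            s2 = make_state(p, species, box=box)
            return interaction_energy(assign_density(s2, m, order), ff.chi)

        delta = 1e-4
        for p in rng.choice(n, size=8, replace=False):
            for k in range(3):
                pp = pos.copy(); pp[p, k] += delta
                pm = pos.copy(); pm[p, k] -= delta
                fd = -(energy(pp) - energy(pm)) / (2 * delta)
                scale = max(abs(fd), abs(F[p, k]), 1e-8)
                assert abs(fd - F[p, k]) / scale < 1e-4


class TestBondedForces:
    def test_dimer_at_rest_length(self, ff_water):
        st = make_state([[1.0, 1.0, 1.0], [1.33, 1.0, 1.0], [1.61, 1.0, 1.0],
                         [1.89, 1.0, 1.0], [2.17, 1.0, 1.0]],
                        ["A", "E", "E", "E", "T"], mol_id=[0] * 5)
        F, E = bonded_forces(st, ff_water)
        assert E == pytest.approx(0.0, abs=1e-20)
        assert np.allclose(F, 0.0, atol=1e-9)

    def test_stretched_bond_hookes_law(self, ff_water):
        """A-E bond stretched by 0.1 nm with k=1250: restoring force 125."""
        ff = ff_water
        st = make_state([[1.0, 1.0, 1.0], [1.43, 1.0, 1.0]], ["A", "E"],
                        mol_id=[0, 0])
        # two-bead molecule is not a standard topology; use a custom one
        from hpfsurf.forcefield import MoleculeTopology
        ff2 = default_adoh_forcefield("W")
        ff2.topologies["DIM"] = MoleculeTopology(
            name="DIM", beads=("A", "E"), bonds=[(0, 1, 1250.0, 0.33)])
        F, E = bonded_forces(st, ff2)
        assert F[0, 0] == pytest.approx(125.0)
        assert F[1, 0] == pytest.approx(-125.0)
        assert E == pytest.approx(0.5 * 1250 * 0.1**2)

    def test_random_chain_matches_finite_difference(self, ff_water):
        rng = np.random.default_rng(3)
        base = np.array([1.0, 2.0, 3.0])
        pos = base + np.cumsum(rng.normal(scale=0.2, size=(5, 3)), axis=0)
        st = make_state(pos, ["A", "E", "E", "E", "T"], mol_id=[0] * 5)
        F, E = bonded_forces(st, ff_water)

        delta = 1e-6
        for p in range(5):
            for k in range(3):
                pp = pos.copy(); pp[p, k] += delta
                pm = pos.copy(); pm[p, k] -= delta
                ep = bonded_forces(make_state(pp, st.species, mol_id=[0] * 5),
                                   ff_water)[1]
                em = bonded_forces(make_state(pm, st.species, mol_id=[0] * 5),
                                   ff_water)[1]
                fd = -(ep - em) / (2 * delta)
                assert fd == pytest.approx(F[p, k], abs=2e-4)

    def test_overlong_bond_rejected(self, ff_water):
        # diagonal separation whose minimum-image length exceeds box/2
        st = make_state([[0.2, 0.2, 0.2], [2.65, 2.65, 2.65]], ["A", "E"],
                        box=5.0, mol_id=[0, 0])
        from hpfsurf.forcefield import MoleculeTopology
        ff2 = default_adoh_forcefield("W")
        ff2.topologies["DIM"] = MoleculeTopology(
            name="DIM", beads=("A", "E"), bonds=[(0, 1, 1250.0, 0.33)])
        with pytest.raises(ValueError, match="minimum image"):
            bonded_forces(st, ff2)


class TestElectrostatics:
    def test_zero_charges_zero_forces(self, ff_water):
        rng = np.random.default_rng(1)
        st = make_state(rng.random((10, 3)) * 5.0, ["W"] * 10,
                        charge=np.zeros(10))
        F = electrostatic_forces(st, ff_water, 10)
        assert np.allclose(F, 0.0)

    def test_opposite_charges_attract_at_coulomb_far_field(self,
                                                           ff_cyclohexane_charged):
        """+0.4/-0.4 e at 3 nm in a 20 nm box, eps_r = 5: force within 5% of
        k_C q^2/(eps_r r^2)."""
        st = make_state([[8.5, 10.0, 10.0], [11.5, 10.0, 10.0]], ["E", "E"],
                        box=20.0, charge=np.array([0.4, -0.4]))
        F = electrostatic_forces(st, ff_cyclohexane_charged, 40)
        expected = KC * 0.4**2 / (5.0 * 3.0**2)
        assert F[0, 0] == pytest.approx(expected, rel=0.05)
        assert F[1, 0] == pytest.approx(-expected, rel=0.05)
        assert np.allclose(F[:, 1:], 0.0, atol=1e-10)

    def test_translation_invariance(self, ff_cyclohexane_charged):
        st = make_state([[8.5, 10.0, 10.0], [11.5, 10.0, 10.0]], ["E", "E"],
                        box=20.0, charge=np.array([0.4, -0.4]))
        F1 = electrostatic_forces(st, ff_cyclohexane_charged, 40)
        st.positions = np.mod(st.positions + np.array([2.5, 1.0, 0.5]), 20.0)
        F2 = electrostatic_forces(st, ff_cyclohexane_charged, 40)
        assert np.allclose(F1, F2, atol=1e-9)

    def test_net_charge_rejected(self, ff_cyclohexane_charged):
        st = make_state([[1.0, 1.0, 1.0]], ["E"], charge=np.array([0.4]))
        with pytest.raises(ValueError, match="net charge"):
            electrostatic_forces(st, ff_cyclohexane_charged, 8)
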