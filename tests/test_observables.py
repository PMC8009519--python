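"""Cluster detection against brute force, RDF normalization, MSD fitting."""

import networkx as nx
import numpy as np
import pytest

from hpfsurf.builder import (make_brownian_trajectory, make_planted_clusters)
from hpfsurf.observables import (aggregate_cluster_series, find_clusters,
                                 fit_diffusion, mean_square_displacement,
                                 radial_distribution)
from hpfsurf.system import SystemState, Trajectory


def brute_force_partition(state, cutoff):
    """O(N^2) bead-pair connectivity, molecules as graph nodes."""
    pos, mol, L = state.positions, state.molecule_id, state.box_edge
    mols = np.unique(mol)
    g = nx.Graph()
    g.add_nodes_from(mols.tolist())
    for i in range(len(pos)):
        for j in range(i + 1, len(pos)):
            if mol[i] == mol[j]:
                continue
            d = pos[i] - pos[j]
            d -= L * np.round(d / L)
            if d @ d < cutoff * cutoff:
                g.add_edge(mol[i], mol[j])
    return sorted(sorted(len(c) for c in nx.connected_components(g)))


class TestFindClusters:
    def test_planted_census_recovered(self, planted_census):
        state, truth = planted_census
        rep = find_clusters(state, 0.8)
        assert rep.histogram == {7: 1, 2: 2, 1: 2}
        assert rep.mean_size == pytest.approx(2.6)
        assert rep.monomer_fraction == pytest.approx(2 / 13)
        # labels must reproduce the planted partition up to renaming
        planted = {}
        for m, lab in enumerate(truth["labels"]):
            planted.setdefault(lab, set()).add(m)
        found = {}
        for m, lab in zip(rep.molecule_ids, rep.labels):
            found.setdefault(lab, set()).add(m)
        assert sorted(map(frozenset, planted.values())) == \
            sorted(map(frozenset, found.values()))

    def test_single_molecule_is_monomer(self):
        state, _ = make_planted_clusters([1], 10.0, seed=1)
        rep = find_clusters(state, 0.8)
        assert rep.histogram == {1: 1}
        assert rep.monomer_fraction == 1.0

    def test_gap_just_below_and_above_cutoff(self):
        """Two molecules at a bead gap straddling the cutoff."""
        def two_mol_state(gap):
            pos = np.array([[5.0, 5.0, 5.0], [5.0 + gap, 5.0, 5.0]])
            return SystemState(
                box_edge=20.0, positions=pos, velocities=np.zeros((2, 3)),
                species=np.array(["A", "A"]), molecule_id=np.array([0, 1]),
                mass=np.ones(2))
        below = find_clusters(two_mol_state(0.79), 0.8)
        above = find_clusters(two_mol_state(0.81), 0.8)
        assert below.histogram == {2: 1}
        assert above.histogram == {1: 2}

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_on_random_configurations(self, seed):
        rng = np.random.default_rng(seed)
        n_mol, L = 40, 6.0
        pos, mol, species = [], [], []
        for m in range(n_mol):
            center = rng.random(3) * L
            for b in range(3):
                pos.append(center + rng.normal(scale=0.3, size=3))
            mol.extend([m] * 3)
            species.extend(["A", "E", "T"])
        state = SystemState(
            box_edge=L, positions=np.mod(np.array(pos), L),
            velocities=np.zeros((3 * n_mol, 3)), species=np.array(species),
            molecule_id=np.array(mol), mass=np.ones(3 * n_mol))
        rep = find_clusters(state, 0.7)
        sizes = sorted(s for s, c in rep.histogram.items() for _ in range(c))
        assert sizes == brute_force_partition(state, 0.7)

    def test_histogram_conserves_molecule_count(self, planted_census):
        state, _ = planted_census
        for cutoff in (0.5, 0.8, 1.5, 3.0):
            rep = find_clusters(state, cutoff)
            assert sum(s * c for s, c in rep.histogram.items()) == 13
            assert rep.mean_size >= 1.0

    def test_bad_cutoff_rejected(self, planted_census):
        state, _ = planted_census
        with pytest.raises(ValueError):
            find_clusters(state, 0.0)
        with pytest.raises(ValueError):
            find_clusters(state, state.box_edge)


class TestAggregateSeries:
    def _report(self, time, histogram):
        from hpfsurf.observables import ClusterReport
        n = sum(s * c for s, c in histogram.items())
        total = sum(histogram.values())
        return ClusterReport(
            time=time, molecule_ids=np.arange(n), labels=np.zeros(n),
            histogram=histogram,
            mean_size=n / total,
            monomer_fraction=histogram.get(1, 0) / total
            if total else 0.0)

    def test_constant_reports_flat_series(self):
        reports = [self._report(t, {1: 4, 3: 2}) for t in (0.0, 1.0, 2.0)]
        series, pooled = aggregate_cluster_series(reports)
        assert np.allclose(series.mean_size, 10 / 6)
        assert pooled.probability.sum() == pytest.approx(1.0)

    def test_alternating_reports_pooled_mean(self):
        reports = [self._report(0.0, {1: 10}), self._report(1.0, {2: 5})]
        _, pooled = aggregate_cluster_series(reports)
        total = pooled.probability.sum()
        assert total == pytest.approx(1.0)
        # pooled counts: 10 monomers + 5 dimers -> mean aggregate size 20/15
        mean = sum(0.5 * (a + b) * p for a, b, p in
                   zip(pooled.size_min, pooled.size_max, pooled.probability))
        assert mean == pytest.approx((10 * 1 + 5 * 2) / 15)

    def test_coarse_binning_width_five(self):
        reports = [self._report(0.0, {1: 3, 4: 1, 7: 2, 12: 1})]
        _, pooled = aggregate_cluster_series(reports, bin_width=5)
        assert list(pooled.size_min[:3]) == [1, 6, 11]
        assert pooled.probability.iloc[0] == pytest.approx(4 / 7)
        assert pooled.probability.iloc[1] == pytest.approx(2 / 7)


def static_traj(pos, box, n_frames=3, species=None, mol_id=None, mass=None):
    n = len(pos)
    return Trajectory(
        box_edge=box, times=np.arange(n_frames, dtype=float),
        positions=np.repeat(np.asarray(pos, dtype=float)[None], n_frames, 0),
        unwrapped=np.repeat(np.asarray(pos, dtype=float)[None], n_frames, 0),
        species=np.array(species if species is not None else ["A"] * n),
        molecule_id=np.asarray(mol_id if mol_id is not None else np.arange(n)),
        mass=mass)


class TestRDF:
    def test_ideal_gas_is_flat_at_unity(self):
        rng = np.random.default_rng(5)
        L, n, frames = 10.0, 2500, 25
        pos = rng.random((frames, n, 3)) * L
        traj = Trajectory(box_edge=L, times=np.arange(frames, dtype=float),
                          positions=pos, unwrapped=pos,
                          species=np.array(["A"] * n),
                          molecule_id=np.arange(n))
        rdf = radial_distribution(traj, "species=A", "species=A",
                                  r_max=4.0, bin_width=0.05)
        mask = rdf.r >= 1.0
        assert np.abs(rdf.g[mask] - 1.0).max() < 0.05

    def test_two_fixed_particles_single_bin_closed_form(self):
        """One pair at distance d: g in that bin is V/(N_A N_B shell)."""
        L, d = 10.0, 2.3
        traj = static_traj([[2.0, 5.0, 5.0], [2.0 + d, 5.0, 5.0]], L,
                           species=["A", "B"])
        rdf = radial_distribution(traj, "species=A", "species=B",
                                  r_max=4.0, bin_width=0.1)
        k = int(d / 0.1)
        shell = 4 / 3 * np.pi * ((0.1 * (k + 1))**3 - (0.1 * k)**3)
        expected = L**3 / shell
        assert rdf.g[k] == pytest.approx(expected, rel=1e-9)
        assert np.count_nonzero(rdf.g) == 1

    def test_identical_selection_excludes_self_pairs(self):
        rng = np.random.default_rng(6)
        traj = static_traj(rng.random((50, 3)) * 10.0, 10.0)
        rdf = radial_distribution(traj, "species=A", "species=A",
                                  r_max=4.0, bin_width=0.05)
        assert np.isfinite(rdf.g).all()
        assert rdf.g[0] == 0.0          # no zero-distance spike

    def test_com_selection_uses_molecule_centers(self):
        # two rigid 2-bead molecules; COM separation 2.05 (mid-bin)
        pos = [[5.0, 5.0, 4.9], [5.0, 5.0, 5.1],
               [7.05, 5.0, 4.9], [7.05, 5.0, 5.1]]
        traj = static_traj(pos, 10.0, species=["A", "A", "A", "A"],
                           mol_id=[0, 0, 1, 1], mass=np.ones(4))
        traj.molecule_name = np.array(["ADOH"] * 4)
        rdf = radial_distribution(traj, "molecule=ADOH and com",
                                  "molecule=ADOH and com",
                                  r_max=4.0, bin_width=0.1)
        assert rdf.g[int(2.05 / 0.1)] > 0
        assert np.count_nonzero(rdf.g) == 1

    def test_rmax_beyond_half_box_rejected(self):
        traj = static_traj([[1.0, 1.0, 1.0]], 10.0)
        with pytest.raises(ValueError):
            radial_distribution(traj, "species=A", "species=A",
                                r_max=6.0, bin_width=0.1)


class TestMSD:
    def test_static_trajectory_gives_zero(self):
        traj = make_brownian_trajectory(100, 0.0, 100, 0.1, 50.0, seed=3)
        fit = fit_diffusion(mean_square_displacement(traj))
        assert fit.D == 0.0
        assert fit.A == 0.0

    def test_brownian_fixture_within_five_percent(self, brownian_half):
        fit = fit_diffusion(mean_square_displacement(brownian_half))
        assert abs(fit.D - 0.5) / 0.5 < 0.05
        assert fit.is_diffusive

    def test_ballistic_motion_flagged_nondiffusive(self):
        """sigma^2 = v^2 t^2 exactly; the log-log slope exposes it."""
        v = 0.2
        t = np.arange(200) * 0.1
        pos = np.zeros((200, 10, 3))
        pos[:, :, 0] = v * t[:, None]
        traj = Trajectory(box_edge=1e6, times=t, positions=pos, unwrapped=pos,
                          species=np.array(["A"] * 10),
                          molecule_id=np.arange(10))
        msd = mean_square_displacement(traj)
        assert np.allclose(msd.msd, (v * msd.lags)**2, rtol=1e-9)
        fit = fit_diffusion(msd)
        assert fit.alpha == pytest.approx(2.0, abs=0.01)
        assert not fit.is_diffusive

    def test_window_outside_lags_rejected(self, brownian_half):
        msd = mean_square_displacement(brownian_half)
        with pytest.raises(ValueError):
            fit_diffusion(msd, window=(1e6, 2e6))

    def test_msd_zero_at_zero_lag_and_nonnegative(self, brownian_half):
        msd = mean_square_displacement(brownian_half)
        assert msd.msd[0] == 0.0
        assert np.all(msd.msd >= 0)
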