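"""Nonbonded energies, SASA, apolar/polar solvation, MM/PBSA summaries."""

import numpy as np
import pytest

from mdnetics.constants import F_COULOMB
from mdnetics.core import Selection, ensemble_from_arrays
from mdnetics.energetics import (ApolarParams, NonbondedParams,
                                 anyframe_contact_pairs, apolar_energy,
                                 group_interaction_energy, mmpbsa_summary,
                                 pair_energy_series, pb_radii,
                                 sasa_shrake_rupley)
from mdnetics.pb import PBSettings, born_energy, polar_energy_fdpb
from mdnetics.synthetic import ToyComplexSpec, _bead_topology, gen_toy_complex


def _two_bead_ensemble(distance, q=(1.0, -1.0), sigma=0.0, eps=0.0, n_frames=3):
    pos = np.array([[0.0, 0.0, 0.0], [distance, 0.0, 0.0]])
    top = _bead_topology(pos, chain_ids=["R", "L"], charges=np.array(q),
                         sigmas=np.full(2, sigma), epsilons=np.full(2, eps),
                         groups={"receptor": [0], "ligand": [1]})
    coords = np.repeat(pos[None], n_frames, axis=0)
    return top, ensemble_from_arrays(top, [coords])


class TestContactGating:
    def _ens(self, distances):
        pos = np.array([[0.0, 0.0, 0.0], [0.5, 0.0, 0.0]])
        top = _bead_topology(pos, groups={"a": [0], "b": [1]})
        coords = np.zeros((len(distances), 2, 3))
        coords[:, 1, 0] = distances
        return top, ensemble_from_arrays(top, [coords])

    def test_inclusive_below_cutoff(self):
        top, ens = self._ens([0.59, 0.59])
        pairs = anyframe_contact_pairs(ens, Selection((0,)), Selection((1,)))
        assert pairs == [(0, 1)]

    def test_beyond_cutoff_excluded(self):
        top, ens = self._ens([0.7, 0.7, 0.7])
        assert anyframe_contact_pairs(ens, Selection((0,)), Selection((1,))) == []

    def test_any_frame_rule(self):
        top, ens = self._ens([0.7, 0.7, 0.55, 0.7])
        assert anyframe_contact_pairs(ens, Selection((0,)), Selection((1,))) == [(0, 1)]

    def test_overlapping_groups_rejected(self):
        top, ens = self._ens([0.5])
        with pytest.raises(ValueError, match="disjoint"):
            anyframe_contact_pairs(ens, Selection((0, 1)), Selection((1,)))


class TestClosedFormEnergies:
    def test_coulomb_two_unit_charges(self):
        top, ens = _two_bead_ensemble(0.5)
        e = group_interaction_energy(ens, Selection((0,)), Selection((1,)))[0]
        np.testing.assert_allclose(e, -277.870916, atol=1e-6)

    def test_lj_zero_at_sigma(self):
        top, ens = _two_bead_ensemble(0.3, q=(0.0, 0.0), sigma=0.3, eps=0.5)
        e = group_interaction_energy(ens, Selection((0,)), Selection((1,)))[0]
        np.testing.assert_allclose(e, 0.0, atol=1e-10)

    def test_lj_minimum_minus_epsilon(self):
        r = 2.0 ** (1.0 / 6.0) * 0.3
        top, ens = _two_bead_ensemble(r, q=(0.0, 0.0), sigma=0.3, eps=0.5)
        e = group_interaction_energy(ens, Selection((0,)), Selection((1,)))[0]
        np.testing.assert_allclose(e, -0.5, atol=1e-10)

    def test_lorentz_berthelot_combination(self):
        # sigma 0.30/0.34 -> pair sigma 0.32; at r = 0.32 the LJ term vanishes
        pos = np.array([[0.0, 0.0, 0.0], [0.32, 0.0, 0.0]])
        top = _bead_topology(pos, charges=np.zeros(2),
                             sigmas=np.array([0.30, 0.34]),
                             epsilons=np.array([0.5, 0.5]),
                             groups={"a": [0], "b": [1]})
        ens = ensemble_from_arrays(top, [pos[None]])
        e = group_interaction_energy(ens, Selection((0,)), Selection((1,)))[0]
        np.testing.assert_allclose(e, 0.0, atol=1e-10)

    def test_zero_charges_zero_energy(self):
        top, ens = _two_bead_ensemble(0.5, q=(0.0, 0.0))
        e = group_interaction_energy(ens, Selection((0,)), Selection((1,)))[0]
        np.testing.assert_allclose(e, 0.0)

    def test_unparameterized_topology_rejected(self):
        top, ens = _two_bead_ensemble(0.5)
        ens.topology.parameters_assigned = False
        with pytest.raises(ValueError, match="parameter"):
            group_interaction_energy(ens, Selection((0,)), Selection((1,)))


class TestPairwiseAdditivity:
    def test_pair_sum_equals_group_energy(self, rng):
        """Ungated, cutoff-free residue-pair energies must sum to the total
        inter-group energy (50-residue toy complex, 100 frames)."""
        n_a, n_b, n_frames = 25, 25, 100
        pos = np.vstack([rng.uniform(0, 3.0, (n_a, 3)),
                         rng.uniform(0.5, 3.5, (n_b, 3)) + [3.5, 0, 0]])
        top = _bead_topology(pos, charges=rng.uniform(-1, 1, n_a + n_b),
                             sigmas=rng.uniform(0.25, 0.35, n_a + n_b),
                             epsilons=rng.uniform(0.1, 0.8, n_a + n_b),
                             groups={"a": np.arange(n_a), "b": np.arange(n_a, n_a + n_b)})
        coords = pos[None] + 0.02 * rng.standard_normal((n_frames, n_a + n_b, 3))
        ens = ensemble_from_arrays(top, [coords])
        ga, gb = Selection(tuple(range(n_a))), Selection(tuple(range(n_a, n_a + n_b)))
        params = NonbondedParams(cutoff=np.inf)
        all_pairs = [(i, j) for i in range(n_a) for j in range(n_a, n_a + n_b)]
        table = pair_energy_series(ens, all_pairs, params=params)
        total_from_pairs = table.table["total"].sum()
        total = np.mean(group_interaction_energy(ens, ga, gb, params=params))
        assert total_from_pairs == pytest.approx(total, rel=1e-6)

    def test_pair_table_is_contact_gated(self):
        top, ens = _two_bead_ensemble(0.5)
        pairs = anyframe_contact_pairs(ens, Selection((0,)), Selection((1,)))
        table = pair_energy_series(ens, pairs)
        assert len(table.table) == len(pairs) == 1


class TestSASA:
    def test_isolated_sphere_area(self):
        per_atom, total = sasa_shrake_rupley(np.zeros((1, 3)), np.array([0.15]),
                                             probe=0.14, n_points=960)
        analytic = 4.0 * np.pi * 0.29**2
        assert total == pytest.approx(analytic, rel=0.01)

    def test_buried_atom_zero(self):
        # central atom enclosed by a shell of 26 overlapping neighbours
        shell = []
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dz in (-1, 0, 1):
                    if (dx, dy, dz) != (0, 0, 0):
                        shell.append([0.25 * dx, 0.25 * dy, 0.25 * dz])
        coords = np.vstack([[0.0, 0.0, 0.0], shell])
        radii = np.full(len(coords), 0.2)
        per_atom, _ = sasa_shrake_rupley(coords, radii, probe=0.14, n_points=960)
        assert per_atom[0] == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_atoms_additive(self):
        coords = np.array([[0.0, 0.0, 0.0], [5.0, 0.0, 0.0]])
        radii = np.array([0.15, 0.2])
        _, total = sasa_shrake_rupley(coords, radii)
        singles = sum(sasa_shrake_rupley(c[None], np.array([r]))[1]
                      for c, r in zip(coords, radii))
        assert total == pytest.approx(singles, rel=1e-12)

    def test_rigid_motion_invariance(self, rng):
        from scipy.spatial.transform import Rotation
        coords = rng.uniform(0, 1, (8, 3))
        radii = rng.uniform(0.12, 0.2, 8)
        _, a = sasa_shrake_rupley(coords, radii)
        R = Rotation.from_euler("xyz", [0.5, 1.0, -0.7]).as_matrix()
        _, b = sasa_shrake_rupley(coords @ R.T + 3.0, radii)
        assert b == pytest.approx(a, rel=1e-6)

    def test_point_count_convergence(self, rng):
        coords = rng.uniform(0, 0.8, (6, 3))
        radii = np.full(6, 0.17)
        _, coarse = sasa_shrake_rupley(coords, radii, n_points=960)
        _, fine = sasa_shrake_rupley(coords, radii, n_points=3840)
        assert abs(coarse - fine) / fine < 0.005

    def test_cross_check_against_mdtraj(self, rng):
        """Independent oracle: mdtraj's Shrake-Rupley on the same cluster."""
        mdtraj = pytest.importorskip("mdtraj")
        coords = rng.uniform(0, 0.6, (5, 3))
        radius = 0.15
        _, ours = sasa_shrake_rupley(coords, np.full(5, radius), probe=0.14,
                                     n_points=3840)
        topo = mdtraj.Topology()
        chain = topo.add_chain()
        res = topo.add_residue("XXX", chain)
        for i in range(5):
            topo.add_atom(f"C{i}", mdtraj.element.carbon, res)
        t = mdtraj.Trajectory(coords[None], topo)
        ref = mdtraj.shrake_rupley(t, probe_radius=0.14, n_sphere_points=3840,
                                   change_radii={"C": radius}).sum()
        assert ours == pytest.approx(float(ref), rel=0.02)


class TestApolarTerm:
    def test_intercept_only_at_zero_sas(self):
        assert apolar_energy(0.0) == pytest.approx(3.84928, abs=1e-9)

    def test_one_nm2(self):
        assert apolar_energy(1.0) == pytest.approx(6.117008, abs=1e-9)

    def test_negative_sas_rejected(self):
        with pytest.raises(ValueError):
            apolar_energy(-0.1)

    def test_intercept_cancels_once_in_binding_difference(self):
        p = ApolarParams()
        sas_c, sas_a, sas_b = 2.0, 1.5, 1.2
        delta = (apolar_energy(sas_c, p) - apolar_energy(sas_a, p)
                 - apolar_energy(sas_b, p))
        assert delta == pytest.approx(p.gamma * (sas_c - sas_a - sas_b) - p.b)


class TestPoissonBoltzmann:
    def test_born_ion_within_tolerance(self):
        settings = PBSettings(spacing=0.04, eps_solute=1.0, eps_solvent=78.5,
                              padding=1.0)
        e = polar_energy_fdpb(np.zeros((1, 3)), np.array([1.0]), np.array([0.2]),
                              settings)
        assert e == pytest.approx(born_energy(1.0, 0.2, 1.0, 78.5), rel=0.05)

    def test_zero_charges_zero_energy(self):
        settings = PBSettings(spacing=0.1, padding=0.5)
        e = polar_energy_fdpb(np.zeros((1, 3)), np.array([0.0]), np.array([0.2]),
                              settings)
        assert e == 0.0

    def test_monotone_in_solvent_dielectric(self):
        values = []
        for eps_out in (2.0, 10.0, 78.5):
            s = PBSettings(spacing=0.05, eps_solute=1.0, eps_solvent=eps_out,
                           padding=0.8)
            values.append(polar_energy_fdpb(np.zeros((1, 3)), np.array([1.0]),
                                            np.array([0.2]), s))
        assert values[0] > values[1] > values[2]  # increasingly negative


class TestMMPBSASummary:
    def _systems(self):
        spec = ToyComplexSpec(
            receptor_positions=[[0.0, 0.0, 0.0], [0.4, 0.0, 0.0]],
            ligand_positions=[[0.0, 0.5, 0.0]],
            receptor_charges=[1.0, -0.3], ligand_charges=[-1.0],
            lj_sigma=0.3, lj_epsilon=0.2, n_frames=8, n_replicas=2,
            mutant_positions={2: (0.0, 0.4, 0.0)})
        return gen_toy_complex(spec)

    def _groups(self, top):
        return (Selection(tuple(top.groups["receptor"])),
                Selection(tuple(top.groups["ligand"])))

    def test_sr_term_equals_group_energy_oracle(self):
        systems = self._systems()
        top, ens = systems["parent"]
        ga, gb = self._groups(top)
        summary = mmpbsa_summary(ens, ga, gb, include_polar=False)
        oracle = np.mean([e.mean() for e in group_interaction_energy(ens, ga, gb)])
        assert summary.delta("E_SR") == pytest.approx(oracle, rel=1e-12)

    def test_identical_systems_zero_difference(self):
        systems = self._systems()
        top, ens = systems["parent"]
        ga, gb = self._groups(top)
        s1 = mmpbsa_summary(ens, ga, gb, include_polar=False)
        s2 = mmpbsa_summary(ens, ga, gb, include_polar=False)
        for term in s1.terms.index:
            assert s1.delta(term) == s2.delta(term)

    def test_mutant_salt_bridge_more_negative(self):
        systems = self._systems()
        vals = {}
        for name, (top, ens) in systems.items():
            ga, gb = self._groups(top)
            vals[name] = mmpbsa_summary(ens, ga, gb, include_polar=False).delta("E_SR")
        assert vals["mutant"] < vals["parent"]

    def test_rigid_motion_invariance_of_deltas(self):
        from scipy.spatial.transform import Rotation
        systems = self._systems()
        top, ens = systems["parent"]
        ga, gb = self._groups(top)
        ref = mmpbsa_summary(ens, ga, gb, include_polar=False)
        R = Rotation.from_euler("zxy", [1.0, -0.4, 0.2]).as_matrix()
        moved = ensemble_from_arrays(
            top, [rep.coords @ R.T + np.array([1.0, 2.0, -0.5])
                  for rep in ens.replicas])
        rot = mmpbsa_summary(moved, ga, gb, include_polar=False)
        for term in ref.terms.index:
            assert rot.delta(term) == pytest.approx(ref.delta(term), abs=1e-8)

    def test_pb_radii_default(self):
        top, _ = _two_bead_ensemble(0.5, sigma=0.3)
        r = pb_radii(top)
        np.testing.assert_allclose(r, 0.3 * 2 ** (1 / 6) / 2)
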