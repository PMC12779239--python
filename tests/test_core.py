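"""Structure I/O, parameter tables, trajectory loading and selections."""

import numpy as np
import pytest

from mdnetics.core import (FormatError, ParameterError, Replica, Selection,
                           SelectionError, TrajectoryEnsemble,
                           ensemble_from_arrays, load_trajectory,
                           read_atom_parameters, read_structure, select,
                           write_atom_parameters, write_structure)


class TestReadStructure:
    def test_single_atom_pdb(self, tmp_path, pdb_atom_line):
        path = tmp_path / "one.pdb"
        path.write_text(pdb_atom_line(1, "CA", "ALA", "A", 1, 1.0, 2.0, 3.0, "C") + "\nEND\n")
        top, frame = read_structure(path)
        assert top.n_atoms == 1
        assert top.n_residues == 1
        # Angstrom -> nm at the boundary
        np.testing.assert_allclose(frame.coordinates[0], [0.1, 0.2, 0.3], atol=1e-6)

    def test_dipeptide_residues_and_order(self, dipeptide):
        top, frame = dipeptide
        assert top.n_residues == 2
        assert [r.name for r in top.residues] == ["ALA", "GLY"]
        names = [a.name for a in top.atoms]
        assert names[:5] == ["N", "CA", "C", "O", "CB"]
        assert top.atoms[1].element == "C"     # CA in an amino acid is carbon
        assert not top.atoms[5].is_heavy       # hydrogens flagged

    def test_malformed_coordinate_names_line(self, tmp_path, pdb_atom_line):
        good = pdb_atom_line(1, "CA", "ALA", "A", 1, 1.0, 2.0, 3.0, "C")
        bad = good[:30] + "  badxxx" + good[38:]
        path = tmp_path / "bad.pdb"
        path.write_text(good + "\n" + bad + "\nEND\n")
        with pytest.raises(FormatError, match="line 2"):
            read_structure(path)

    def test_zero_atoms_is_error(self, tmp_path):
        path = tmp_path / "empty.pdb"
        path.write_text("REMARK nothing here\nEND\n")
        with pytest.raises(FormatError, match="no ATOM"):
            read_structure(path)


class TestRoundTrip:
    def test_write_read_preserves_structure(self, tmp_path, dipeptide):
        top, frame = dipeptide
        out = tmp_path / "rt.pdb"
        write_structure(out, top, frame)
        top2, frame2 = read_structure(out)
        assert [a.name for a in top2.atoms] == [a.name for a in top.atoms]
        assert [a.residue_index for a in top2.atoms] == [a.residue_index for a in top.atoms]
        assert [r.author_seq_id for r in top2.residues] == [r.author_seq_id for r in top.residues]
        # coordinates preserved to 1e-3 Angstrom = 1e-4 nm
        np.testing.assert_allclose(frame2.coordinates, frame.coordinates, atol=1e-4)

    def test_multi_model_round_trip(self, tmp_path, dipeptide):
        top, frame = dipeptide
        frames = [frame, type(frame)(frame.coordinates + 0.1, time=1.0)]
        out = tmp_path / "mm.pdb"
        write_structure(out, top, frames)
        traj = load_trajectory(out, top, discard_ns=0.0)
        assert traj.replicas[0].n_frames == 2


class TestParameterTable:
    def _table(self, tmp_path, rows):
        path = tmp_path / "params.csv"
        path.write_text("chain,residue_index,atom_name,mass,charge,sigma,epsilon\n"
                        + "\n".join(rows) + "\n")
        return path

    def test_assignment_and_group_charge(self, tmp_path, pdb_atom_line):
        pdb = tmp_path / "one.pdb"
        pdb.write_text(pdb_atom_line(1, "CA", "ALA", "A", 1, 0.0, 0.0, 0.0, "C") + "\nEND\n")
        top, _ = read_structure(pdb)
        top.set_group("solo", [0])
        table = self._table(tmp_path, ["A,1,CA,12.0,1.0,0.3,0.5"])
        top2 = read_atom_parameters(table, top)
        assert top2.atoms[0].charge == 1.0
        assert top2.group_charges["solo"] == pytest.approx(1.0)

    def test_missing_atom_names_the_atom(self, tmp_path, dipeptide_pdb):
        top, _ = read_structure(dipeptide_pdb)
        table = self._table(tmp_path, ["A,1,N,14.0,-0.4,0.32,0.7"])  # covers one atom only
        with pytest.raises(ParameterError, match="CA"):
            read_atom_parameters(table, top)

    def test_duplicate_row_is_ambiguous(self, tmp_path, pdb_atom_line):
        pdb = tmp_path / "one.pdb"
        pdb.write_text(pdb_atom_line(1, "CA", "ALA", "A", 1, 0.0, 0.0, 0.0, "C") + "\nEND\n")
        top, _ = read_structure(pdb)
        table = self._table(tmp_path, ["A,1,CA,12.0,1.0,0.3,0.5",
                                       "A,1,CA,12.0,0.5,0.3,0.5"])
        with pytest.raises(ParameterError, match="duplicate"):
            read_atom_parameters(table, top)

    def test_parameter_round_trip(self, tmp_path, dipeptide):
        top, _ = dipeptide
        rows = []
        for a in top.atoms:
            res = top.residues[a.residue_index]
            rows.append(f"{a.chain_id},{res.author_seq_id},{a.name},"
                        f"{a.mass},0.1,0.3,0.2")
        top2 = read_atom_parameters(self._table(tmp_path, rows), top)
        out = tmp_path / "rt_params.csv"
        write_atom_parameters(out, top2)
        top3 = read_atom_parameters(out, top)
        np.testing.assert_allclose(top3.charges, top2.charges)


class TestLoadTrajectory:
    def test_discard_window_bookkeeping(self, dipeptide, tmp_path):
        top, frame = dipeptide
        n = 1000
        coords = np.repeat(frame.coordinates[None], n, axis=0)
        times = np.arange(n) * 1000.0       # 1 ns spacing
        np.savez(tmp_path / "traj.npz", coords=coords, times=times)
        traj = load_trajectory(tmp_path / "traj.npz", top, discard_ns=200.0)
        # 1000 frames at 1 ns spacing, 200 ns discard -> 800 analysis frames
        assert traj.n_analysis_frames == [800]
        assert traj.total_frames == 1000

    def test_atom_count_mismatch(self, dipeptide, tmp_path):
        top, _ = dipeptide
        np.savez(tmp_path / "bad.npz", coords=np.zeros((3, top.n_atoms + 1, 3)),
                 times=np.arange(3.0))
        with pytest.raises(ValueError, match="atoms"):
            load_trajectory(tmp_path / "bad.npz", top, discard_ns=0)

    def test_non_monotone_times_rejected(self, dipeptide):
        top, frame = dipeptide
        coords = np.repeat(frame.coordinates[None], 3, axis=0)
        with pytest.raises(ValueError, match="strictly increasing"):
            Replica(coords, np.array([0.0, 2.0, 1.0]))

    def test_adapter_entry_point(self, dipeptide):
        top, frame = dipeptide
        coords = np.repeat(frame.coordinates[None], 5, axis=0)
        ens = ensemble_from_arrays(top, [coords, coords])
        assert ens.n_replicas == 2
        assert ens.replicas[0].n_frames == 5


class TestSelection:
    def test_name_ca(self, dipeptide):
        top, _ = dipeptide
        sel = select(top, "name CA")
        assert len(sel) == 2
        assert [top.atoms[i].name for i in sel.atom_indices] == ["CA", "CA"]

    def test_heavy_excludes_hydrogens(self, dipeptide):
        top, _ = dipeptide
        sel = select(top, "heavy")
        assert all(top.atoms[i].element != "H" for i in sel.atom_indices)
        assert len(sel) == 9

    def test_reversed_range_is_parse_error(self, dipeptide):
        top, _ = dipeptide
        with pytest.raises(SelectionError, match="reversed"):
            select(top, "chain A and resid 5-3")

    def test_unknown_keyword_reports_position(self, dipeptide):
        top, _ = dipeptide
        with pytest.raises(SelectionError, match="position"):
            select(top, "name CA and bogus")

    def test_empty_selection_warns(self, dipeptide):
        top, _ = dipeptide
        with pytest.warns(UserWarning, match="no atoms"):
            sel = select(top, "chain Z")
        assert len(sel) == 0

    def test_idempotent_and_order_stable(self, dipeptide):
        top, _ = dipeptide
        a = select(top, "resid 1-2 and heavy")
        b = select(top, "resid 1-2 and heavy")
        assert a.atom_indices == b.atom_indices
        assert list(a.atom_indices) == sorted(a.atom_indices)

    def test_group_union_covers_without_duplicates(self, dipeptide):
        top, _ = dipeptide
        top.set_group("first", select(top, "resid 1").indices)
        top.set_group("second", select(top, "resid 2").indices)
        union = select(top, "group first or group second")
        assert len(union) == top.n_atoms
        assert len(set(union.atom_indices)) == len(union.atom_indices)

    def test_duplicate_indices_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            Selection((0, 0, 1))
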