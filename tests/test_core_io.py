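"""Containers, atom selection and file round trips."""

import numpy as np
import pytest

import nrtraj as nt
from nrtraj.errors import (ConsistencyError, ParseError, SelectionError,
                           StructureError)


def _tiny_topology(**kw):
    defaults = dict(atom_id=[1, 2, 3], name=["N", "CA", "C"],
                    element=["N", "C", "C"], residue_number=[1, 1, 1],
                    residue_name=["ALA"] * 3, chain=["A"] * 3)
    defaults.update(kw)
    return nt.Topology(**defaults)


class TestTopologyInvariants:
    def test_duplicate_atom_ids_rejected(self):
        with pytest.raises(StructureError):
            _tiny_topology(atom_id=[1, 1, 2])

    def test_non_carbon_calpha_rejected(self):
        with pytest.raises(StructureError):
            _tiny_topology(roles={"c_alpha": [True, False, False]})

    def test_small_ring_rejected(self):
        with pytest.raises(StructureError):
            _tiny_topology(rings=[[1, 2, 3]])

    def test_frame_atom_count_must_match(self, ideal_helix):
        top, frame = ideal_helix
        short = nt.Frame(index=1, time=0.0, coordinates=frame.coordinates[:-1])
        with pytest.raises(StructureError):
            nt.Trajectory(topology=top, frames=[short])

    def test_nonfinite_coordinates_rejected(self):
        with pytest.raises(StructureError):
            nt.Frame(index=0, time=0.0, coordinates=[[np.nan, 0, 0]])


class TestSelectAtoms:
    def test_span_calpha_count(self, agonist_bundle, anchors):
        ids = nt.select_atoms(agonist_bundle.topology, span=anchors.h12, role="c_alpha")
        assert len(ids) == len(anchors.h12)

    def test_empty_span_is_empty_not_error(self, agonist_bundle):
        ids = nt.select_atoms(agonist_bundle.topology,
                              residue_range=(900, 950), role="c_alpha")
        assert ids == []

    def test_deterministic_and_ordered(self, agonist_bundle, anchors):
        a = nt.select_atoms(agonist_bundle.topology, span=anchors.h10)
        b = nt.select_atoms(agonist_bundle.topology, span=anchors.h10)
        assert a == b == sorted(a)

    def test_unknown_field_raises(self, agonist_bundle):
        with pytest.raises(SelectionError):
            nt.select_atoms(agonist_bundle.topology, colour="red")

    def test_unknown_role_raises(self, agonist_bundle):
        with pytest.raises(SelectionError):
            nt.select_atoms(agonist_bundle.topology, role="magic")


class TestStructureRoundTrip:
    def test_multi_model_round_trip(self, tmp_path, agonist_bundle):
        path = tmp_path / "b.pdb"
        sub = nt.Trajectory(topology=agonist_bundle.topology,
                            frames=agonist_bundle.frames[:3])
        nt.write_structure(sub, path)
        back = nt.read_structure(path)
        assert back.n_frames == 3
        assert back.topology == sub.topology
        # 3-decimal PDB quantization (half-step 5e-4) plus float32 storage
        assert np.abs(back.coordinates() - sub.coordinates()).max() < 6e-4
        # writing what was read reproduces the file byte for byte
        path2 = tmp_path / "b2.pdb"
        nt.write_structure(back, path2)
        assert path.read_text() == path2.read_text()

    def test_single_model_dialect(self, tmp_path, ideal_helix):
        top, frame = ideal_helix
        path = tmp_path / "one.pdb"
        nt.write_structure(nt.Trajectory(topology=top, frames=[frame]), path)
        traj = nt.read_structure(path, dialect="pdb")
        assert traj.n_frames == 1
        assert traj.topology.n_atoms == top.n_atoms

    def test_model_atom_mismatch_is_structure_error(self, tmp_path, agonist_bundle):
        path = tmp_path / "broken.pdb"
        sub = nt.Trajectory(topology=agonist_bundle.topology,
                            frames=agonist_bundle.frames[:2])
        nt.write_structure(sub, path)
        lines = path.read_text().splitlines(True)
        second_model = [i for i, l in enumerate(lines) if l.startswith("MODEL")][1]
        drop = next(i for i in range(second_model, len(lines))
                    if lines[i].startswith("ATOM"))
        del lines[drop]
        path.write_text("".join(lines))
        with pytest.raises(StructureError):
            nt.read_structure(path)

    def test_single_dialect_rejects_multi_model(self, tmp_path, agonist_bundle):
        path = tmp_path / "multi.pdb"
        nt.write_structure(nt.Trajectory(topology=agonist_bundle.topology,
                                         frames=agonist_bundle.frames[:2]), path)
        with pytest.raises(StructureError):
            nt.read_structure(path, dialect="pdb")

    def test_roles_populated_on_read(self, tmp_path, planted_complex):
        path = tmp_path / "cplx.pdb"
        nt.write_structure(nt.Trajectory(topology=planted_complex.topology,
                                         frames=planted_complex.frames[:1]), path)
        top = nt.read_structure(path).topology
        assert top.roles["ligand"].sum() == planted_complex.topology.roles["ligand"].sum()
        assert top.roles["water"].any()
        assert top.roles["hbond_acceptor"].any()


class TestEnergyTableIO:
    def test_round_trip(self, tmp_path):
        table = nt.synth_energy_table(2, 5, mean=-12.0, sd=1.0, hac=23, seed=4)
        path = tmp_path / "e.csv"
        nt.write_energy_table(table, path)
        back = nt.read_energy_table(path)
        assert back.hac == 23
        assert np.allclose(back.records[["dg_total", "dg_lipo"]].to_numpy(),
                           table.records[["dg_total", "dg_lipo"]].to_numpy())

    def test_non_numeric_cell_names_row(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("frame,replica,dg_total,dg_lipo,dg_coulomb,dg_hbond\n"
                        "0,0,-10,-6,-3,-1\n1,0,NA,-6,-3,-1\n")
        with pytest.raises(ParseError, match="row 2"):
            nt.read_energy_table(path)

    def test_duplicate_key_rejected(self, tmp_path):
        path = tmp_path / "dup.csv"
        path.write_text("frame,replica,dg_total,dg_lipo,dg_coulomb,dg_hbond\n"
                        "0,0,-10,-6,-3,-1\n0,0,-11,-6,-3,-1\n")
        with pytest.raises(ConsistencyError):
            nt.read_energy_table(path)

    def test_missing_column_rejected(self, tmp_path):
        path = tmp_path / "mis.csv"
        path.write_text("frame,replica,dg_total\n0,0,-10\n")
        with pytest.raises(ParseError, match="missing"):
            nt.read_energy_table(path)


class TestAnchorConfig:
    def test_yaml_round_trip(self, tmp_path):
        anchors = {"ERalpha": nt.default_anchors("ERalpha"),
                   "GR": nt.default_anchors("GR")}
        path = tmp_path / "anchors.yaml"
        nt.save_anchors(anchors, path)
        back = nt.load_anchors(path)
        assert back["GR"].h12.first_residue == 751
        assert back["GR"].h12.last_residue == 764
        assert back["ERalpha"].h3b.first_residue == 348

    def test_default_anchor_tables(self):
        era = nt.default_anchors("ERalpha")
        assert (era.h10.first_residue, era.h10.last_residue) == (518, 532)
        gr = nt.default_anchors("GR")
        assert (gr.h3b.first_residue, gr.h3b.last_residue) == (556, 579)
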