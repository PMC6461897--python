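"""I/O: PDBQT multi-pose parsing, the pose-table dialect, receptor PDB,
and report serialization round-trips."""

import json

import numpy as np
import pytest

from poserank import (
    AtomRecord,
    ClusteringParams,
    LigandPose,
    ParseError,
    PoseEnsemble,
    ThermoParams,
    cluster_poses,
    rank_report,
    read_pdbqt_poses,
    read_pose_table,
    read_receptor_pdb,
    read_report_json,
    score_clusters,
    write_pose_table,
    write_report,
)
from poserank.pose_io import element_mass

from .conftest import make_pdbqt, point_ensemble


class TestPdbqt:
    def test_three_models_parse_in_order_with_energies(self, three_model_pdbqt):
        ens = read_pdbqt_poses(three_model_pdbqt, ligand_id="lig")
        assert len(ens) == 3
        assert [p.pose_index for p in ens.poses] == [1, 2, 3]
        assert [p.energy for p in ens.poses] == [-7.9, -7.5, -6.0]
        assert all(len(p.atoms) == 2 for p in ens.poses)

    def test_single_atom_coordinates_read_from_fixed_columns(self, tmp_path):
        path = tmp_path / "one.pdbqt"
        path.write_text(make_pdbqt([(-5.0, [("C1", 1.0, 2.0, 3.0)])]))
        ens = read_pdbqt_poses(path, "one")
        assert np.array_equal(ens.poses[0].atoms[0].coord, [1.0, 2.0, 3.0])

    def test_energy_sign_preserved_verbatim(self, tmp_path):
        path = tmp_path / "pos.pdbqt"
        path.write_text(make_pdbqt([(3.25, [("C1", 0.0, 0.0, 0.0)])]))
        assert read_pdbqt_poses(path, "x").poses[0].energy == 3.25

    def test_missing_energy_remark_names_the_block(self, tmp_path):
        text = make_pdbqt([(-7.0, [("C1", 0, 0, 0)]), (-6.0, [("C1", 1, 1, 1)])])
        text = "\n".join(l for l in text.splitlines()
                         if not (l.startswith("REMARK") and "-6.000" in l))
        path = tmp_path / "bad.pdbqt"
        path.write_text(text)
        with pytest.raises(ParseError, match="MODEL 2"):
            read_pdbqt_poses(path, "bad")

    def test_malformed_coordinate_reports_line_number(self, tmp_path):
        text = make_pdbqt([(-7.0, [("C1", 0, 0, 0)])])
        text = text.replace("   0.000   0.000   0.000", "   x.xxx   0.000   0.000")
        path = tmp_path / "bad.pdbqt"
        path.write_text(text)
        with pytest.raises(ParseError, match="line"):
            read_pdbqt_poses(path, "bad")

    def test_modelless_file_with_energy_remark_is_single_pose(self, tmp_path):
        text = make_pdbqt([(-4.2, [("C1", 1, 2, 3)])])
        text = "\n".join(l for l in text.splitlines()
                         if not l.startswith(("MODEL", "ENDMDL"))) + "\n"
        path = tmp_path / "flat.pdbqt"
        path.write_text(text)
        ens = read_pdbqt_poses(path, "flat")
        assert len(ens) == 1 and ens.poses[0].energy == -4.2

    def test_modelless_file_without_remark_errors(self, tmp_path):
        path = tmp_path / "flat.pdbqt"
        path.write_text("ATOM      1  C1  LIG A   1       1.000   2.000   3.000\n")
        with pytest.raises(ParseError):
            read_pdbqt_poses(path, "flat")


class TestPoseTable:
    def test_round_trip_is_bit_exact(self, tmp_path):
        ens = point_ensemble(
            [(0.123456789012345, -1.0, 2.0), (5.0, 0.0, 0.0)], [-9.87654321, -5.0]
        )
        path = tmp_path / "poses.tsv"
        write_pose_table(ens, path)
        assert read_pose_table(path) == ens

    def test_table_from_pdbqt_parse_equals_pdbqt_parse(self, three_model_pdbqt, tmp_path):
        ens = read_pdbqt_poses(three_model_pdbqt, "lig")
        path = tmp_path / "poses.tsv"
        write_pose_table(ens, path)
        assert read_pose_table(path) == ens

    def test_conflicting_energies_for_one_pose_error(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text(
            "ligand_id\tpose_id\tenergy\tatom_name\telement\tx\ty\tz\n"
            "lig\t1\t-5.0\tC1\tC\t0\t0\t0\n"
            "lig\t1\t-6.0\tC2\tC\t1\t0\t0\n"
        )
        with pytest.raises(ParseError, match="conflicting"):
            read_pose_table(path)

    def test_empty_data_section_errors(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("# comment\nligand_id\tpose_id\tenergy\tatom_name\telement\tx\ty\tz\n")
        with pytest.raises(ParseError, match="no poses"):
            read_pose_table(path)

    def test_missing_columns_error(self, tmp_path):
        path = tmp_path / "cols.tsv"
        path.write_text("ligand_id\tpose_id\tenergy\nlig\t1\t-5.0\n")
        with pytest.raises(ParseError, match="missing columns"):
            read_pose_table(path)


class TestReceptorPdb:
    def test_toy_three_residue_fixture(self, tmp_path):
        from poserank import make_toy_receptor

        _, pdb = make_toy_receptor(
            [("VAL", 178, (0.0, 0.0, 0.0)),
             ("SER", 181, (5.0, 5.0, 5.0)),
             ("GLN", 185, (10.0, 0.0, 0.0))]
        )
        path = tmp_path / "toy.pdb"
        path.write_text(pdb)
        rec = read_receptor_pdb(path)
        groups = {(a.chain_id, a.residue_number) for a in rec.atoms}
        assert len(groups) == 3
        cas = {a.residue_number: tuple(a.coord) for a in rec.atoms if a.name == "CA"}
        assert cas[181] == (5.0, 5.0, 5.0)

    def test_altloc_keeps_exactly_one_copy(self, tmp_path):
        lines = [
            "ATOM      1  N   SER A 181       0.000   0.000   0.000  1.00  0.00           N",
            "ATOM      2  CA ASER A 181       1.000   0.000   0.000  0.60  0.00           C",
            "ATOM      3  CA BSER A 181       1.200   0.000   0.000  0.40  0.00           C",
            "ATOM      4  C   SER A 181       2.000   0.000   0.000  1.00  0.00           C",
            "END",
        ]
        path = tmp_path / "alt.pdb"
        path.write_text("\n".join(lines) + "\n")
        rec = read_receptor_pdb(path)
        cas = [a for a in rec.atoms if a.name == "CA"]
        assert len(cas) == 1
        assert tuple(cas[0].coord) == (1.0, 0.0, 0.0)

    def test_non_pdb_text_is_a_parse_error(self, tmp_path):
        path = tmp_path / "junk.pdb"
        path.write_text("this is not\ta PDB file\n")
        with pytest.raises(ParseError):
            read_receptor_pdb(path)


class TestReport:
    @pytest.fixture
    def report(self):
        ens = point_ensemble([(0, 0, 0), (1, 0, 0), (30, 0, 0)], [-9.0, -8.0, -5.0])
        clusters = cluster_poses(ens, ClusteringParams(radius=4.0))
        scored = score_clusters(clusters, ThermoParams())
        return rank_report({"toy": scored}, {"radius": 4.0})

    def test_tsv_has_header_and_one_row_per_cluster(self, report, tmp_path):
        path = tmp_path / "report.tsv"
        write_report(report, path, format="tsv")
        lines = path.read_text().splitlines()
        assert lines[0].startswith("ligand_id\tcluster_rank")
        assert len(lines) == 1 + 2  # two clusters

    def test_json_round_trip_preserves_values(self, report, tmp_path):
        path = tmp_path / "report.json"
        write_report(report, path, format="json")
        loaded = read_report_json(path)
        assert loaded["parameters"] == {"radius": 4.0}
        rows = loaded["clusters"]
        assert [r["n_poses"] for r in rows] == [2, 1]
        assert rows[0]["e_min"] == -9.0
        # round-trip through json again is identical
        assert json.loads(json.dumps(loaded)) == loaded

    def test_empty_report_errors(self, tmp_path):
        from poserank import RescoreReport

        with pytest.raises(ValueError, match="empty"):
            write_report(RescoreReport(entries=[]), tmp_path / "x.tsv")

    def test_unknown_format_errors(self, report, tmp_path):
        with pytest.raises(ValueError, match="format"):
            write_report(report, tmp_path / "x.xml", format="xml")


class TestDomainInvariants:
    def test_heterogeneous_atom_names_rejected_unless_overridden(self):
        p1 = LigandPose(1, [AtomRecord("C1", "C", (0, 0, 0))], -5.0)
        p2 = LigandPose(2, [AtomRecord("N1", "N", (1, 0, 0))], -4.0)
        with pytest.raises(ValueError, match="atom"):
            PoseEnsemble("lig", [p1, p2])
        ens = PoseEnsemble("lig", [p1, p2], allow_heterogeneous=True)
        assert len(ens) == 2

    def test_pose_index_must_be_unique_and_increasing(self):
        mk = lambda i: LigandPose(i, [AtomRecord("C1", "C", (0, 0, 0))], -5.0)
        with pytest.raises(ValueError):
            PoseEnsemble("lig", [mk(2), mk(1)])

    def test_nonfinite_coordinates_and_energies_rejected(self):
        with pytest.raises(ValueError):
            AtomRecord("C1", "C", (0.0, float("nan"), 0.0))
        with pytest.raises(ValueError):
            LigandPose(1, [AtomRecord("C1", "C", (0, 0, 0))], float("inf"))

    def test_unknown_element_falls_back_to_carbon_mass(self):
        assert element_mass("Xq") == element_mass("C")
        assert element_mass("O") == pytest.approx(15.999)
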