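"""File round trips and model-annotation extraction."""

import logging

import numpy as np
import pytest

from ssetopo.correspondence import CorrespondenceSet, MatchRecord
from ssetopo.errors import InputError
from ssetopo.sse_io import (
    DensityStick,
    GroundTruth,
    read_ground_truth,
    read_model_sses,
    read_sticks,
    read_topology,
    write_ground_truth,
    write_model_sses,
    write_sticks,
    write_topology,
)
from ssetopo.synthetic import SimulationConfig, generate_model

from conftest import straight_sse


@pytest.fixture
def model_on_disk(tmp_path):
    sses = generate_model(SimulationConfig(n_helices=3, n_strands=2, seed=4))
    pdb = tmp_path / "model.pdb"
    ann = tmp_path / "annotation.tsv"
    write_model_sses(sses, pdb, ann)
    return sses, pdb, ann


class TestReadModelSSEs:
    def test_id_assignment_convention(self, model_on_disk):
        _, pdb, _ = model_on_disk
        sses = read_model_sses(pdb)
        assert [s.sse_id for s in sses if s.sse_type == "helix"] == ["H1", "H2", "H3"]
        assert [s.sse_id for s in sses if s.sse_type == "strand"] == ["S1", "S2"]

    def test_coordinates_round_trip(self, model_on_disk):
        orig, pdb, _ = model_on_disk
        sses = {s.sse_id: s for s in read_model_sses(pdb)}
        for s in orig:
            # PDB fixed-format coordinates carry 3 decimals
            np.testing.assert_allclose(
                sses[s.sse_id].calpha_coords, s.calpha_coords, atol=5e-4
            )

    def test_mmcif_equivalent(self, model_on_disk, tmp_path):
        orig, pdb, _ = model_on_disk
        cif = tmp_path / "model.cif"
        write_model_sses(orig, cif)
        assert [s.sse_id for s in read_model_sses(cif)] == [
            s.sse_id for s in read_model_sses(pdb)
        ]

    def test_sidecar_overrides_and_order_invariance(self, model_on_disk, tmp_path):
        # same annotation rows in scrambled order must give identical SSEs
        _, pdb, ann = model_on_disk
        lines = ann.read_text().splitlines()
        scrambled = tmp_path / "scrambled.tsv"
        scrambled.write_text("\n".join([lines[0]] + lines[1:][::-1]) + "\n")
        a = read_model_sses(pdb, annotation=ann)
        b = read_model_sses(pdb, annotation=scrambled)
        assert [(s.sse_id, s.residue_range) for s in a] == [
            (s.sse_id, s.residue_range) for s in b
        ]

    def test_annotation_model_mismatch(self, model_on_disk, tmp_path):
        _, pdb, _ = model_on_disk
        bad = tmp_path / "bad.tsv"
        bad.write_text("chain\tstart_res\tend_res\ttype\nA\t9000\t9005\tH\n")
        with pytest.raises(InputError, match="mismatch"):
            read_model_sses(pdb, annotation=bad)

    def test_short_sse_dropped_with_warning(self, model_on_disk, tmp_path, caplog):
        sses, pdb, _ = model_on_disk
        start = sses[0].residue_range[0]
        ann = tmp_path / "short.tsv"
        ann.write_text(
            "chain\tstart_res\tend_res\ttype\n"
            f"A\t{start}\t{start + 1}\tH\n"          # 2 residues: dropped
            f"A\t{start}\t{start + 4}\tS\n"
        )
        with caplog.at_level(logging.WARNING, logger="ssetopo.sse_io"):
            result = read_model_sses(pdb, annotation=ann)
        assert [s.sse_id for s in result] == ["S1"]
        assert any("dropping" in r.message for r in caplog.records)

    def test_zero_sses_after_filter(self, model_on_disk, tmp_path):
        sses, pdb, _ = model_on_disk
        start = sses[0].residue_range[0]
        ann = tmp_path / "all_short.tsv"
        ann.write_text(f"chain\tstart_res\tend_res\ttype\nA\t{start}\t{start + 1}\tH\n")
        with pytest.raises(InputError, match="zero SSEs"):
            read_model_sses(pdb, annotation=ann)

    def test_unparseable_file(self, tmp_path):
        bad = tmp_path / "junk.pdb"
        bad.write_text("this is not a structure\n")
        with pytest.raises(InputError):
            read_model_sses(bad)


class TestSticks:
    def _sticks(self):
        return [
            DensityStick("V1", "helix", np.arange(24, dtype=float).reshape(8, 3)),
            DensityStick("V2", "strand",
                         np.arange(12, dtype=float).reshape(4, 3) / 7.0,
                         confidence=0.5),
        ]

    @pytest.mark.parametrize("ext", ["json", "tsv"])
    def test_round_trip(self, tmp_path, ext):
        path = tmp_path / f"sticks.{ext}"
        write_sticks(self._sticks(), path)
        back = read_sticks(path)
        assert [s.stick_id for s in back] == ["V1", "V2"]
        assert [s.sse_type for s in back] == ["helix", "strand"]
        assert back[1].confidence == 0.5
        for a, b in zip(self._sticks(), back):
            np.testing.assert_allclose(b.axis_points, a.axis_points, atol=1e-6)

    def test_unknown_type_rejected(self, tmp_path):
        path = tmp_path / "sticks.json"
        path.write_text('[{"stick_id": "V1", "sse_type": "coil", "points": [[0,0,0]]}]')
        with pytest.raises(InputError, match="unknown SSE type"):
            read_sticks(path)

    def test_empty_point_list_rejected(self, tmp_path):
        path = tmp_path / "sticks.json"
        path.write_text('[{"stick_id": "V1", "sse_type": "helix", "points": []}]')
        with pytest.raises(InputError):
            read_sticks(path)

    def test_duplicate_id_rejected(self, tmp_path):
        path = tmp_path / "sticks.json"
        path.write_text(
            '[{"stick_id": "V1", "sse_type": "helix", "points": [[0,0,0]]},'
            ' {"stick_id": "V1", "sse_type": "helix", "points": [[1,1,1]]}]'
        )
        with pytest.raises(InputError, match="duplicate"):
            read_sticks(path)


class TestTopologyTables:
    def test_empty_set(self, tmp_path):
        path = tmp_path / "topo.tsv"
        write_topology(CorrespondenceSet(), path)
        back = read_topology(path)
        assert back.pairs == [] and back.unmatched_sses == []

    def test_sorted_rows_and_round_trip(self, tmp_path):
        cs = CorrespondenceSet(
            pairs=[
                MatchRecord("H2", "V9", score=1.25, direction=-1),
                MatchRecord("H10", "V2", score=0.5, direction=+1),
                MatchRecord("H1", "V1", score=0.0, direction=+1),
            ],
            unmatched_sses=["S1"],
            unmatched_sticks=["V7"],
        )
        path = tmp_path / "topo.tsv"
        write_topology(cs, path)
        rows = path.read_text().splitlines()
        # natural sort: H1, H2, H10 — not lexicographic
        assert [r.split("\t")[0] for r in rows[1:4]] == ["H1", "H2", "H10"]
        back = read_topology(path)
        assert {(p.sse_id, p.stick_id, p.direction, p.score) for p in back.pairs} == {
            ("H1", "V1", 1, 0.0), ("H2", "V9", -1, 1.25), ("H10", "V2", 1, 0.5)
        }
        assert back.unmatched_sses == ["S1"]
        assert back.unmatched_sticks == ["V7"]

    def test_ground_truth_round_trip(self, tmp_path):
        truth = GroundTruth(
            pairs=[("H1", "V1", 1), ("H2", "V3", -1)],
            unmatched_sses=["H3"],
            unmatched_sticks=["V2"],
        )
        path = tmp_path / "truth.tsv"
        write_ground_truth(truth, path)
        back = read_ground_truth(path)
        assert set(back.pairs) == set(truth.pairs)
        assert back.unmatched_sses == ["H3"]
        assert back.unmatched_sticks == ["V2"]

    def test_ground_truth_one_to_one_enforced(self):
        with pytest.raises(InputError):
            GroundTruth(pairs=[("H1", "V1", 1), ("H1", "V2", 1)])


def test_model_sse_invariants():
    sse = straight_sse(n=4)
    assert sse.residue_count == 4
    assert np.linalg.norm(sse.axis_vector) == pytest.approx(1.0, abs=1e-9)
    with pytest.raises(InputError):
        straight_sse(n=1)
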