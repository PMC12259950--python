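"""Structure model: Kabat labels, region maps, PDB round trips, sequences."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from vhhforge.structure import (
    Atom,
    PdbFormatError,
    RegionMap,
    ResidueLabel,
    StructureComplex,
    StructureError,
    annotate_regions,
    chain_sequence,
    default_region_map,
    read_pdb,
    write_pdb,
)
from vhhforge.toyworld import make_toy_complex, ToySpec

from conftest import make_atom, make_mini_complex, far_template


class TestResidueLabel:
    def test_insertion_sorts_after_bare_number(self):
        labels = [ResidueLabel.parse(s) for s in ["53", "52a", "52"]]
        assert sorted(str(l) for l in sorted(labels)) != None
        assert [str(l) for l in sorted(labels)] == ["52", "52a", "53"]

    @given(st.integers(min_value=1, max_value=999),
           st.sampled_from(["", "a", "b", "f"]))
    def test_parse_str_round_trip(self, number, ins):
        label = ResidueLabel(number, ins)
        assert ResidueLabel.parse(str(label)) == label

    def test_bad_label_rejected(self):
        with pytest.raises(StructureError):
            ResidueLabel.parse("abc")


class TestRegionMap:
    def test_default_map_cdr_lengths(self):
        rm = default_region_map()
        lengths = rm.cdr_lengths()
        assert lengths["CDR1"] == 7
        assert lengths["CDR2"] == 7
        assert lengths["CDR3"] == 10

    @pytest.mark.parametrize("n", [6, 12])
    def test_cdr3_length_configurable(self, n):
        assert default_region_map(n).cdr_lengths()["CDR3"] == n

    @pytest.mark.parametrize("n", [5, 13])
    def test_cdr3_length_out_of_range(self, n):
        with pytest.raises(StructureError):
            default_region_map(n)

    def test_fixed_labels_equal_fr_union(self):
        rm = default_region_map()
        fr = {lab for tag, labs in rm.segments if tag.startswith("FR") for lab in labs}
        assert rm.fixed_labels == fr

    def test_empty_cdr_rejected(self):
        with pytest.raises(StructureError):
            RegionMap.from_segments(
                [("FR1", ["1", "2"]), ("CDR1", []), ("CDR2", ["3"]), ("CDR3", ["4"])]
            )

    def test_overlapping_segments_rejected(self):
        with pytest.raises(StructureError):
            RegionMap.from_segments(
                [("FR1", ["1"]), ("CDR1", ["1"]), ("CDR2", ["2"]), ("CDR3", ["3"])]
            )


class TestAnnotation:
    def test_default_map_on_toy_scaffold_gives_7_residue_cdr1(self, toy_complex):
        cdr1 = [lab for lab in toy_complex.designed_labels()
                if toy_complex.tag_of(lab) == "CDR1"]
        assert len(cdr1) == 7

    def test_annotation_is_a_partition(self, toy_complex):
        tags = [toy_complex.tag_of(lab) for lab in toy_complex.designed_labels()]
        assert len(tags) == len(toy_complex.designed_labels())
        assert set(tags) <= {"FR1", "CDR1", "FR2", "CDR2", "FR3", "CDR3", "FR4"}

    def test_map_label_missing_from_structure_errors(self):
        cx = make_mini_complex(far_template(), [(0, 0, 0)])
        bigger = RegionMap.from_segments(
            [("FR1", ["1"]), ("CDR1", ["2"]), ("FR2", ["3"]), ("CDR2", ["4"]),
             ("FR3", ["5"]), ("CDR3", ["6"]), ("FR4", ["7", "8"])]
        )
        with pytest.raises(StructureError, match="absent"):
            annotate_regions(cx, bigger)

    def test_untagged_residue_errors(self):
        cx = make_mini_complex(far_template(), [(0, 0, 0)])
        smaller = RegionMap.from_segments(
            [("FR1", ["1"]), ("CDR1", ["2"]), ("CDR2", ["4"]),
             ("FR3", ["5"]), ("CDR3", ["6"]), ("FR4", ["7"])]
        )
        with pytest.raises(StructureError, match="without a region tag"):
            annotate_regions(cx, smaller)


class TestChainSequence:
    def test_cdr1_filter_length(self, toy_complex):
        assert len(chain_sequence(toy_complex, {"CDR1"})) == 7

    def test_no_filter_concatenates_regions(self, toy_complex):
        full = chain_sequence(toy_complex)
        parts = [chain_sequence(toy_complex, {tag})
                 for tag in ("FR1", "CDR1", "FR2", "CDR2", "FR3", "CDR3", "FR4")]
        assert full == "".join(parts)

    def test_empty_filter_empty_string(self, toy_complex):
        assert chain_sequence(toy_complex, set()) == ""

    def test_unknown_residue_name_errors(self):
        template = far_template()
        cx = make_mini_complex(template, [(0, 0, 0)])
        bad = tuple(
            a if str(a.residue_label) != "1"
            else type(a)(a.serial, a.element, a.coords, a.radius,
                         a.residue_label, "XXX", a.chain_id, a.name)
            for a in cx.designed_chain
        )
        cx2 = StructureComplex(bad, cx.target_chain, cx.region_map)
        with pytest.raises(StructureError, match="unknown residue"):
            chain_sequence(cx2)


class TestPdbIO:
    def test_minimal_two_atom_parse(self, tmp_path):
        cx = StructureComplex(
            (make_atom(1, (0, 0, 0), chain="A"),),
            (make_atom(2, (4, 0, 0), chain="B"),),
        )
        path = write_pdb(cx, tmp_path / "mini.pdb")
        back = read_pdb(path)
        assert len(back.designed_chain) == 1
        assert len(back.target_chain) == 1

    def test_round_trip_preserves_labels_and_coords(self, toy_complex, tmp_path):
        path = write_pdb(toy_complex, tmp_path / "toy.pdb")
        back = read_pdb(path)
        assert back.n_atoms() == toy_complex.n_atoms()
        assert back.designed_labels() == toy_complex.designed_labels()
        for a, b in zip(toy_complex.all_atoms(), back.all_atoms()):
            assert a.chain_id == b.chain_id
            assert a.residue_label == b.residue_label
            assert np.allclose(a.xyz, b.xyz, atol=1e-3)

    def test_insertion_code_written_to_pdb_column(self, tmp_path):
        cx = StructureComplex(
            (make_atom(1, (0, 0, 0), label="52a"),),
            (make_atom(2, (9, 0, 0), chain="B"),),
        )
        path = write_pdb(cx, tmp_path / "ins.pdb")
        atom_lines = [l for l in path.read_text().splitlines()
                      if l.startswith("ATOM") and " A " in l]
        assert atom_lines[0][26] == "A"  # insertion-code column

    def test_single_chain_file_rejected(self, tmp_path):
        path = tmp_path / "one.pdb"
        cx = StructureComplex(
            (make_atom(1, (0, 0, 0)),), (make_atom(2, (5, 0, 0), chain="B"),)
        )
        write_pdb(cx, path)
        text = "\n".join(l for l in path.read_text().splitlines() if " B " not in l)
        path.write_text(text + "\n")
        with pytest.raises(StructureError, match="two chains"):
            read_pdb(path)

    def test_unparseable_atom_line_names_line_number(self, tmp_path):
        path = tmp_path / "bad.pdb"
        path.write_text(
            "ATOM      1  CA  GLY A   1       0.000   0.000   0.000  1.00  0.00           C\n"
            "ATOM      2  CA  GLY B   1       4.000   bad     0.000  1.00  0.00           C\n"
        )
        with pytest.raises(PdbFormatError, match="line 2"):
            read_pdb(path)

    def test_empty_designed_chain_rejected(self):
        with pytest.raises(StructureError, match="non-empty"):
            StructureComplex((), (make_atom(1, (0, 0, 0), chain="B"),))


class TestAtomInvariants:
    def test_nonpositive_radius_rejected(self):
        with pytest.raises(StructureError):
            make_atom(1, (0, 0, 0), radius=0.0)

    def test_nonfinite_coords_rejected(self):
        with pytest.raises(StructureError):
            make_atom(1, (0, float("nan"), 0))

    def test_duplicate_serials_rejected(self):
        with pytest.raises(StructureError, match="unique"):
            StructureComplex(
                (make_atom(1, (0, 0, 0)),),
                (make_atom(1, (5, 0, 0), chain="B"),),
            )
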