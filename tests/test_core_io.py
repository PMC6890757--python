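"""Format dialects, coordinate conventions and input validation."""

from __future__ import annotations

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cladescape import (
    AnnotationParseError,
    ScaffoldTable,
    TERecord,
    parse_support_tree,
    read_count_matrix,
    read_scaffolds,
    read_te_annotations,
    write_te_annotations,
)


class TestTEAnnotations:
    def test_gff3_is_converted_to_zero_based_half_open(self, tmp_path):
        path = tmp_path / "te.gff3"
        path.write_text(
            "##gff-version 3\n"
            "sc1\tsrc\tTE\t101\t200\t.\t+\t.\tclade=sire;family=Ty1/Copia;ID=te1\n"
        )
        (rec,) = read_te_annotations(path, format="gff3")
        assert (rec.start, rec.end) == (100, 200)
        assert rec.clade == "sire"
        assert rec.family == "Ty1/Copia"
        assert rec.length == 100

    def test_bed_passes_through_unchanged(self, tmp_path):
        path = tmp_path / "te.bed"
        path.write_text("sc1\t100\t200\tclade=oryco\n")
        (rec,) = read_te_annotations(path, format="bed")
        assert (rec.start, rec.end, rec.clade) == (100, 200, "oryco")

    def test_reversed_coordinates_error_names_the_line(self, tmp_path):
        path = tmp_path / "te.gff3"
        path.write_text(
            "sc1\tsrc\tTE\t10\t20\t.\t.\t.\tclade=sire\n"
            "sc1\tsrc\tTE\t300\t200\t.\t.\t.\tclade=sire\n"
        )
        with pytest.raises(AnnotationParseError, match="line 2"):
            read_te_annotations(path, format="gff3")

    def test_missing_clade_attribute_errors_with_line(self, tmp_path):
        path = tmp_path / "te.gff3"
        path.write_text("sc1\tsrc\tTE\t10\t20\t.\t.\t.\tID=x\n")
        with pytest.raises(AnnotationParseError, match="line 1"):
            read_te_annotations(path, format="gff3")

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        data=st.lists(
            st.tuples(
                st.integers(0, 2),  # scaffold
                st.integers(0, 10_000),  # start
                st.integers(1, 500),  # length
                st.sampled_from(["sire", "oryco", "athila"]),
            ),
            min_size=1,
            max_size=30,
        ),
        fmt=st.sampled_from(["gff3", "bed"]),
    )
    def test_round_trip_preserves_records(self, data, fmt, tmp_path_factory):
        records = [
            TERecord(f"sc{s}", start, start + length, clade, source_id=f"t{i}")
            for i, (s, start, length, clade) in enumerate(data)
        ]
        path = tmp_path_factory.mktemp("rt") / f"x.{fmt}"
        write_te_annotations(records, path, format=fmt)
        assert read_te_annotations(path, format=fmt) == records

    def test_gff3_bed_coordinate_relation(self, tmp_path):
        records = [TERecord("sc1", 999, 2_000, "sire")]
        gff3, bed = tmp_path / "x.gff3", tmp_path / "x.bed"
        write_te_annotations(records, gff3, format="gff3")
        write_te_annotations(records, bed, format="bed")
        gff_fields = gff3.read_text().splitlines()[1].split("\t")
        bed_fields = bed.read_text().splitlines()[0].split("\t")
        assert int(gff_fields[3]) == int(bed_fields[1]) + 1
        assert int(gff_fields[4]) == int(bed_fields[2])


class TestScaffolds:
    def test_fasta_lengths_and_total(self, tmp_path):
        path = tmp_path / "g.fasta"
        path.write_text(">sc1\n" + "ACGT" * 250 + "\n>sc2\n" + "A" * 2000 + "\n")
        table = read_scaffolds(path, mode="fasta")
        assert table.lengths == {"sc1": 1000, "sc2": 2000}
        assert table.total_length == 3000
        assert table.sequence("sc1").startswith("ACGT")

    def test_lengths_tsv_supports_assembly_scale_totals(self, tmp_path):
        path = tmp_path / "lengths.tsv"
        path.write_text("sc1\t7084225540\n")
        table = read_scaffolds(path, mode="lengths_tsv")
        assert table.total_length == 7_084_225_540
        assert not table.has_sequences

    def test_duplicate_scaffold_id_rejected(self, tmp_path):
        path = tmp_path / "g.fasta"
        path.write_text(">sc1\nACGT\n>sc1\nACGT\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_scaffolds(path, mode="fasta")

    def test_empty_file_rejected(self, tmp_path):
        path = tmp_path / "g.fasta"
        path.write_text("")
        with pytest.raises(ValueError):
            read_scaffolds(path, mode="fasta")

    def test_record_beyond_scaffold_end_rejected(self):
        table = ScaffoldTable({"sc1": 100})
        with pytest.raises(ValueError, match="exceeds"):
            table.validate_records([TERecord("sc1", 50, 150, "sire")])


class TestSupportTrees:
    def test_percent_scale_normalized_whole_file(self):
        tree = parse_support_tree("((A_1,A_2)95,(B_1,C_1)40);")
        assert sorted(s for s in tree.internal_supports()) == [0.40, 0.95]

    def test_unit_scale_left_unchanged(self):
        tree = parse_support_tree("((A_1,A_2)0.95,B_1);")
        assert tree.internal_supports() == [0.95]

    def test_absent_support_is_none_not_zero(self):
        tree = parse_support_tree("((A_1,A_2),B_1);")
        assert tree.internal_supports() == [None]

    def test_underscores_in_tip_labels_preserved(self):
        tree = parse_support_tree("((Tc_001,Tc_002)90,Cs_001);")
        assert sorted(tree.tip_labels) == ["Cs_001", "Tc_001", "Tc_002"]

    def test_unbalanced_parentheses_raise(self):
        with pytest.raises(ValueError, match="[Nn]ewick"):
            parse_support_tree("((A_1,A_2)95,(B_1;")

    def test_duplicate_tip_labels_raise(self):
        with pytest.raises(ValueError, match="duplicate"):
            parse_support_tree("((A_1,A_1)95,B_1);")

    def test_clone_preserves_supports_and_tips(self):
        tree = parse_support_tree("(((A_1,A_2)95,A_3)80,(B_1,B_2)40,C_1);")
        clone = tree.clone()
        assert sorted(clone.tip_labels) == sorted(tree.tip_labels)
        assert clone.internal_supports() == tree.internal_supports()


class TestCountMatrix:
    HEADER = "interpro_id\tname\tTc\tCs\tAa\tHa\tNt\tOs\tAt\n"

    def test_printed_row_parses(self, tmp_path):
        path = tmp_path / "counts.tsv"
        path.write_text(
            self.HEADER
            + "IPR036041\tRibosome-inactivating protein\t98\t7\t16\t0\t0\t17\t0\n"
        )
        matrix = read_count_matrix(path)
        assert matrix.row("IPR036041") == {
            "Tc": 98, "Cs": 7, "Aa": 16, "Ha": 0, "Nt": 0, "Os": 17, "At": 0
        }
        assert matrix.name_of("IPR036041") == "Ribosome-inactivating protein"

    def test_single_genus_matrix_rejected(self, tmp_path):
        path = tmp_path / "counts.tsv"
        path.write_text("interpro_id\tname\tTc\nIPR1\tx\t5\n")
        with pytest.raises(ValueError):
            read_count_matrix(path)

    def test_negative_cell_rejected(self, tmp_path):
        path = tmp_path / "counts.tsv"
        path.write_text(self.HEADER + "IPR1\tx\t5\t-1\t2\t3\t4\t5\t6\n")
        with pytest.raises(ValueError, match="negative"):
            read_count_matrix(path)

    def test_non_integer_cell_names_row_and_column(self, tmp_path):
        path = tmp_path / "counts.tsv"
        path.write_text(self.HEADER + "IPR1\tx\t5\tmany\t2\t3\t4\t5\t6\n")
        with pytest.raises(ValueError, match="IPR1.*Cs"):
            read_count_matrix(path)
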