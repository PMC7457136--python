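import pytest

from globinkit import foldmap
from globinkit.foldmap import (
    FoldCoordinate,
    ReferenceFold,
    build_fold_mapping,
    key_position_column,
    nterm_extension_length,
    reorder_segments,
)
from globinkit.seqio import Alignment, SequenceRecord

SEGMENT_RANK = {name: i for i, name in enumerate(foldmap.SEGMENT_ORDER)}


def two_row(ref_row, query_row, fold):
    return Alignment(
        [
            SequenceRecord(fold.reference_id, "", ref_row),
            SequenceRecord("q", "", query_row),
        ]
    )


class TestFoldCoordinate:
    @pytest.mark.parametrize("label,seg,idx", [("B12", "B", 12), ("CD3", "CD", 3), ("E10", "E", 10), ("NT5", "NT", 5)])
    def test_parse_and_render(self, label, seg, idx):
        c = FoldCoordinate.parse(label)
        assert (c.segment, c.index) == (seg, idx)
        assert str(c) == label

    @pytest.mark.parametrize("bad", ["Z9", "IJ3", "B0", "12B", "E"])
    def test_invalid_labels_rejected(self, bad):
        with pytest.raises(ValueError):
            FoldCoordinate.parse(bad)


class TestReferenceFold:
    def test_overlapping_segments_rejected(self):
        with pytest.raises(ValueError, match="overlaps"):
            ReferenceFold("r", [("A", 1, 10), ("B", 5, 20)])

    def test_out_of_order_segments_rejected(self):
        with pytest.raises(ValueError, match="order"):
            ReferenceFold("r", [("B", 1, 10), ("A", 11, 20)])

    def test_uncovered_residues_get_flanking_loop(self):
        fold = ReferenceFold("r", [("C", 1, 5), ("D", 9, 12)])
        coords = fold.residue_coordinates(14)
        assert str(coords[4]) == "C5"
        assert [str(c) for c in coords[5:8]] == ["CD1", "CD2", "CD3"]
        assert str(coords[8]) == "D1"
        assert [str(c) for c in coords[12:]] == ["CT1", "CT2"]


class TestBuildFoldMapping:
    def test_reference_maps_to_its_own_segmentation(self, default_fold, reference_record, reference_mapping):
        for name, start, end in default_fold.segments:
            for res in range(start, end + 1):
                c = reference_mapping.coordinate_of(res)
                assert c.segment == name
                assert c.index == res - start + 1

    def test_insertion_in_cd_loop_continues_indices(self):
        fold = ReferenceFold("r", [("C", 1, 3), ("CD", 4, 6), ("D", 7, 9)])
        # query inserts 3 residues after the 2nd CD-loop residue
        aln = two_row("WWWLLL---III", "WWWLLKKKLIII", fold)
        m = build_fold_mapping(aln, fold)["q"]
        labels = [str(c) for c in m.coords]
        assert labels[3:9] == ["CD1", "CD2", "CD3", "CD4", "CD5", "CD6"]

    def test_nterm_extension_of_195_columns_maps_to_nt(self, default_fold, reference_record):
        # long N-terminal extension, like the arthropod GbX average of 195 aa
        ext = "A" * 195
        aln = two_row(
            "-" * 195 + reference_record.residues,
            ext + reference_record.residues,
            default_fold,
        )
        m = build_fold_mapping(aln, default_fold)["q"]
        assert [c.segment for c in m.coords[:195]] == ["NT"] * 195
        assert nterm_extension_length(m) == 195

    def test_missing_reference_rejected(self, default_fold):
        aln = Alignment([SequenceRecord("q", "", "MGH")])
        with pytest.raises(ValueError, match="missing"):
            build_fold_mapping(aln, default_fold)

    def test_segments_beyond_reference_rejected(self):
        fold = ReferenceFold("r", [("A", 1, 50)])
        aln = Alignment([SequenceRecord("r", "", "MGHMGH")])
        with pytest.raises(ValueError, match="segments extend"):
            build_fold_mapping(aln, fold)

    def test_mapping_is_monotone_in_segment_order(self, study_family):
        mappings = study_family.fold_mappings()
        for m in mappings.values():
            ranks = [SEGMENT_RANK[c.segment] for c in m.coords if c is not None]
            assert ranks == sorted(ranks)


class TestKeyPositionColumn:
    def test_e7_counts_seven_residues_into_helix_e(self):
        # helix E declared to start at reference residue 58: E7 = residue 64
        fold = ReferenceFold("r", [("E", 58, 80)])
        ref = SequenceRecord("r", "", "W" * 80)
        aln = Alignment([ref])
        assert key_position_column(fold, aln, "E7") == 63  # 0-based column

    def test_cd1_is_first_loop_residue(self, default_fold, reference_record):
        aln = Alignment([reference_record])
        start, _ = default_fold.segment_span("CD")
        assert key_position_column(default_fold, aln, "CD1") == start - 1

    def test_unknown_segment_rejected(self, default_fold, reference_record):
        aln = Alignment([reference_record])
        with pytest.raises(ValueError):
            key_position_column(default_fold, aln, "Z9")

    def test_exhaustive_agreement_with_segmentation(self, default_fold, reference_record):
        """Every declared coordinate resolves to the column where the
        reference carries that coordinate (identity alignment)."""
        aln = Alignment([reference_record])
        for name, start, end in default_fold.segments:
            for idx in range(1, end - start + 2):
                col = key_position_column(default_fold, aln, f"{name}{idx}")
                assert col == start + idx - 2


class TestNtermExtension:
    def test_reference_has_no_extension(self, reference_mapping):
        assert nterm_extension_length(reference_mapping) == 0

    def test_all_nt_degenerate_mapping(self):
        fold = ReferenceFold("r", [("A", 6, 10)])
        aln = two_row("VVVVVWWWWW", "KKKKK-----", fold)
        m = build_fold_mapping(aln, fold)["q"]
        assert nterm_extension_length(m) == len(m)


class TestReorderSegments:
    SEQ = SequenceRecord("s", "", "ACDEFGHIKLMNPQRSTVWY")

    def test_identity_permutation(self):
        out = reorder_segments(self.SEQ, {"A": (1, 10), "B": (11, 20)}, ["A", "B"])
        assert out.residues == self.SEQ.residues

    def test_swap(self):
        out = reorder_segments(self.SEQ, {"H": (1, 8), "A": (9, 18)}, ["A", "H"])
        assert out.residues == self.SEQ.residues[8:18] + self.SEQ.residues[:8]

    def test_residues_outside_spans_dropped(self):
        out = reorder_segments(self.SEQ, {"X": (3, 5)}, ["X"])
        assert out.residues == "DEF"

    def test_overlapping_spans_rejected(self):
        with pytest.raises(ValueError, match="overlaps"):
            reorder_segments(self.SEQ, {"A": (1, 10), "B": (10, 15)}, ["A", "B"])

    def test_unknown_name_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            reorder_segments(self.SEQ, {"A": (1, 5)}, ["A", "Z"])

    def test_permutation_round_trip(self):
        """Applying a permutation and then its inverse on the re-spanned
        result restores the original concatenation."""
        spans = {"a": (1, 4), "b": (5, 9), "c": (10, 14), "d": (15, 20)}
        order = ["c", "a", "d", "b"]
        once = reorder_segments(self.SEQ, spans, order)
        # spans of each named block inside the permuted sequence
        respans = {}
        pos = 1
        for name in order:
            s, e = spans[name]
            respans[name] = (pos, pos + (e - s))
            pos += e - s + 1
        back = reorder_segments(once, respans, ["a", "b", "c", "d"])
        assert back.residues == self.SEQ.residues
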