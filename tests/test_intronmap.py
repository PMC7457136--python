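import pytest

from globinkit import intronmap, synthdata
from globinkit.foldmap import ReferenceFold, build_fold_mapping
from globinkit.intronmap import (
    IntronSite,
    classify_intron_sites,
    extract_intron_offsets,
    label_gene_introns,
    label_intron,
    summarize_variant_sites,
)
from globinkit.seqio import Alignment, GeneModel, SequenceRecord


def make_site(label, gene_id="g", conservation=None):
    """An IntronSite with internally consistent bookkeeping for one label."""
    coord, phase = label.rsplit(".", 1)
    phase = int(phase)
    # place the site on an arbitrary consistent offset
    residue = 5
    offset = (residue - 1) * 3 + (phase if phase else 0)
    if phase == 0:
        residue = offset // 3 + 1
    site = IntronSite(
        gene_id=gene_id, cds_offset=offset, residue_index=residue,
        phase=phase, fold_label=label, conservation=conservation,
    )
    return site


class TestExtractOffsets:
    def test_plus_strand_two_exons(self):
        m = GeneModel("g", "c", "+", [(1, 35), (100, 139)])
        assert extract_intron_offsets(m) == [35]

    def test_minus_strand_mirrored(self):
        # exon coding lengths 35 and 40 in translation order on '-'
        m = GeneModel("g", "c", "-", [(1, 40), (100, 134)])
        assert extract_intron_offsets(m) == [35]

    def test_single_exon_is_intronless(self):
        assert extract_intron_offsets(GeneModel("g", "c", "+", [(1, 99)])) == []

    def test_three_exons_cumulative(self):
        m = GeneModel("g", "c", "+", [(1, 36), (50, 85), (100, 129)])
        assert extract_intron_offsets(m) == [36, 72]


@pytest.fixture(scope="module")
def mapping():
    # B starts at residue 1 so that residue 12 is helix-B position 12;
    # G starts at residue 30 so that residue 36 is G7
    fold = ReferenceFold("r", [("B", 1, 20), ("G", 30, 40)])
    ref = SequenceRecord("r", "", "W" * 40)
    return build_fold_mapping(Alignment([ref]), fold)["r"]


class TestLabelIntron:

    def test_b12_2_definition(self, mapping):
        """An intron after coding nucleotide 35 lies between codon positions
        2 and 3 of residue 12; with residue 12 at helix-B position 12 the
        label is B12.2."""
        site = label_intron(35, mapping)
        assert (site.phase, site.residue_index, site.fold_label) == (2, 12, "B12.2")

    def test_g7_0_definition(self, mapping):
        """A phase-0 intron immediately preceding the codon of helix-G
        residue 7 (protein residue 36) is G7.0."""
        site = label_intron((36 - 1) * 3, mapping)
        assert (site.phase, site.residue_index, site.fold_label) == (0, 36, "G7.0")

    def test_offset_beyond_cds_rejected(self, mapping):
        with pytest.raises(ValueError, match="outside coding sequence"):
            label_intron(3 * 40, mapping)
        with pytest.raises(ValueError, match="outside coding sequence"):
            label_intron(0, mapping)

    def test_exhaustive_offsets_match_base_walking_oracle(self, reference_mapping):
        """Labels over every valid offset agree with an oracle that walks
        the coding sequence one base at a time, tracking codon and phase."""
        n = len(reference_mapping)
        for offset in range(1, 3 * n):
            site = label_intron(offset, reference_mapping)
            # oracle: walk codons base by base
            codon, within = 1, 0
            for _ in range(offset):
                within += 1
                if within == 3:
                    codon, within = codon + 1, 0
            expected_residue = codon if within else codon  # phase 0 precedes next codon
            assert site.phase == within
            assert site.residue_index == expected_residue
            coord = reference_mapping.coordinate_of(expected_residue)
            assert site.fold_label == f"{coord}.{within}"


class TestStrandInvariance:
    def test_gene_and_mirror_yield_identical_labels(self, reference_record, reference_mapping):
        plans = {reference_record.id: ["B12.2", "E10.2", "G7.0"]}
        maps = {reference_record.id: reference_mapping}
        for_plus = synthdata.simulate_gene_models([reference_record], maps, plans, strands={reference_record.id: "+"})
        for_minus = synthdata.simulate_gene_models([reference_record], maps, plans, strands={reference_record.id: "-"})
        labels_plus = [s.fold_label for s in label_gene_introns(for_plus[0].gene_model, reference_mapping)]
        labels_minus = [s.fold_label for s in label_gene_introns(for_minus[0].gene_model, reference_mapping)]
        assert labels_plus == labels_minus == ["B12.2", "E10.2", "G7.0"]


class TestClassify:
    @pytest.mark.parametrize(
        "label,globin_class,expected",
        [
            ("B12.2", "HbL", "ancestral"),
            ("B12.2", "GbXL", "ancestral"),
            ("G7.0", "GbX", "ancestral"),
            ("E10.2", "GbX", "ancestral"),
            ("E10.2", "HbL", "variant"),
            ("E10.2", "GbXL", "variant"),
            ("CD3.2", "GbXL", "variant"),
            ("D7.0", "HbL", "variant"),
        ],
    )
    def test_conservation_rules(self, label, globin_class, expected):
        (site,) = classify_intron_sites([make_site(label)], globin_class)
        assert site.conservation == expected

    def test_unknown_class_rejected(self):
        with pytest.raises(ValueError, match="unknown globin class"):
            classify_intron_sites([make_site("B12.2")], "Ngb")


class TestSummary:
    def test_e_helix_variants_counted(self):
        sites = [
            make_site("E9.1", conservation="variant"),
            make_site("E15.0", conservation="variant"),
            make_site("B12.2", conservation="ancestral"),
        ]
        s = summarize_variant_sites(sites)
        assert s.total_variant_sites == 2
        assert s.per_segment == {"E": 2}
        assert s.in_or_between_e_f == 2

    def test_empty_input(self):
        s = summarize_variant_sites([])
        assert s.total_variant_sites == 0
        assert s.in_or_between_e_f == 0

    def test_duplicate_labels_counted_once(self):
        sites = [
            make_site("E9.1", gene_id=g, conservation="variant") for g in "abc"
        ]
        assert summarize_variant_sites(sites).total_variant_sites == 1

    def test_per_segment_counts_sum_to_total(self):
        labels = ["E9.1", "E15.0", "CD3.2", "D7.0", "A12.2", "NT4.1", "F3.2"]
        sites = [make_site(lab, conservation="variant") for lab in labels]
        s = summarize_variant_sites(sites)
        assert sum(s.per_segment.values()) == s.total_variant_sites == len(labels)

    def test_planted_fifteen_of_eighteen_in_ef_region(self):
        """A set with 18 distinct variant positions, 15 planted in or
        between helices E and F, reports 15 of 18."""
        ef_labels = [f"E{i}.1" for i in range(1, 8)] + [f"EF{i}.0" for i in range(1, 5)] + [f"F{i}.2" for i in range(1, 5)]
        other_labels = ["A3.1", "B7.0", "GH2.2"]
        assert len(ef_labels) == 15 and len(other_labels) == 3
        sites = [make_site(lab, conservation="variant") for lab in ef_labels + other_labels]
        s = summarize_variant_sites(sites)
        assert s.total_variant_sites == 18
        assert s.in_or_between_e_f == 15

    def test_flanking_loop_flag_widens_rule(self):
        sites = [
            make_site("DE2.1", conservation="variant"),
            make_site("FG1.0", conservation="variant"),
        ]
        assert summarize_variant_sites(sites).in_or_between_e_f == 0
        assert summarize_variant_sites(sites, include_flanking_loops=True).in_or_between_e_f == 2


class TestPlantedRoundTrip:
    @pytest.mark.parametrize("strand", ["+", "-"])
    @pytest.mark.parametrize("plan", [[], ["B12.2", "G7.0"], ["B12.2", "E10.2", "G7.0"], ["CD3.2"], ["NT2.1"]])
    def test_planted_labels_recovered(self, strand, plan, reference_record, reference_mapping, default_fold):
        rec = SequenceRecord("q", "", "KLM" + reference_record.residues)
        aln = Alignment([
            SequenceRecord(default_fold.reference_id, "", "---" + reference_record.residues),
            SequenceRecord("q", "", rec.residues),
        ])
        mapping = build_fold_mapping(aln, default_fold)["q"]
        genes = synthdata.simulate_gene_models([rec], {"q": mapping}, {"q": plan}, strands={"q": strand})
        got = [s.fold_label for s in label_gene_introns(genes[0].gene_model, mapping)]
        assert got == sorted(plan)
        assert len(genes[0].gene_model.cds_exons) == len(plan) + 1
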