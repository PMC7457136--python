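"""Intron positions expressed in helix-coordinate/phase notation.

An intron interrupting a coding sequence is named by the fold coordinate of
the affected codon plus the intron phase: "B12.2" is an intron between codon
positions 2 and 3 of the 12th residue of helix B; "G7.0" sits immediately
before the codon of the 7th residue of helix G (phase 0 = between codons,
phase 1/2 = after the first/second base of the codon).

Two intron positions, B12.2 and G7.0, are ancestral across metazoan (and
even plant) globin genes; a third central intron at E10.2 is additionally
ancestral within the globin X (GbX) lineage.  Every other position is
treated as a lineage-specific variant.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .foldmap import FoldCoordinate, FoldMapping
from .seqio import GeneModel

#: intron positions ancestral for every globin class
ANCESTRAL_LABELS = frozenset({"B12.2", "G7.0"})
#: additionally ancestral positions per class
CLASS_ANCESTRAL = {"GbX": frozenset({"E10.2"})}
GLOBIN_CLASSES = ("HbL", "GbX", "GbXL")

#: default operationalization of "in or between helices E and F"
EF_SEGMENTS = frozenset({"E", "EF", "F"})
EF_SEGMENTS_WIDE = EF_SEGMENTS | {"DE", "FG"}


@dataclass
class IntronSite:
    """One intron, located on the coding sequence and on the fold.

    ``cds_offset`` counts coding nucleotides preceding the intron (1-based
    count); phase = cds_offset mod 3.  ``residue_index`` is the protein
    residue whose codon context defines the label: for phase 1/2 the codon
    the intron interrupts, for phase 0 the codon the intron precedes.
    """

    gene_id: str
    cds_offset: int
    residue_index: int
    phase: int
    fold_label: str
    conservation: str | None = None

    def __post_init__(self) -> None:
        if self.phase != self.cds_offset % 3:
            raise ValueError(
                f"{self.gene_id}: phase {self.phase} != cds_offset {self.cds_offset} mod 3"
            )
        expected = (
            self.cds_offset // 3 + 1 if self.phase == 0
            else (self.cds_offset - 1) // 3 + 1
        )
        if self.residue_index != expected:
            raise ValueError(
                f"{self.gene_id}: residue_index {self.residue_index} inconsistent "
                f"with cds_offset {self.cds_offset}"
            )

    @property
    def segment(self) -> str:
        return FoldCoordinate.parse(self.fold_label.rsplit(".", 1)[0]).segment


@dataclass
class IntronSummary:
    """Counts of distinct variant intron positions across a dataset."""

    per_segment: dict[str, int] = field(default_factory=dict)
    total_variant_sites: int = 0
    in_or_between_e_f: int = 0
    variant_labels: list[str] = field(default_factory=list)


def extract_intron_offsets(gene_model: GeneModel) -> list[int]:
    """CDS-nucleotide offsets of the introns of a gene model.

    Offsets are counted on the strand-ordered concatenated coding sequence;
    a single-exon (intronless) gene yields the empty list.
    """
    exons = gene_model.exons_in_translation_order
    if not exons:
        raise ValueError(f"gene {gene_model.gene_id}: no CDS exons")
    offsets: list[int] = []
    total = 0
    for start, end in exons[:-1]:
        length = end - start + 1
        if length <= 0:
            raise ValueError(f"gene {gene_model.gene_id}: zero-length exon")
        total += length
        offsets.append(total)
    return offsets


def label_intron(
    cds_offset: int, fold_mapping: FoldMapping, gene_id: str = ""
) -> IntronSite:
    """Express one intron position as a fold-coordinate/phase label.

    Valid offsets are 1 .. 3N-1 for a protein of N residues: an offset of
    3N would place the "intron" after the final codon, outside the coding
    sequence proper.
    """
    n_res = len(fold_mapping)
    if not 1 <= cds_offset <= 3 * n_res - 1:
        raise ValueError(
            f"cds_offset {cds_offset} outside coding sequence "
            f"(valid 1..{3 * n_res - 1} for {n_res} residues)"
        )
    phase = cds_offset % 3
    if phase == 0:
        residue_index = cds_offset // 3 + 1
    else:
        residue_index = (cds_offset - 1) // 3 + 1
    coord = fold_mapping.coordinate_of(residue_index)
    if coord is None:
        raise ValueError(
            f"residue {residue_index} of {fold_mapping.sequence_id!r} has no fold coordinate"
        )
    return IntronSite(
        gene_id=gene_id or fold_mapping.sequence_id,
        cds_offset=cds_offset,
        residue_index=residue_index,
        phase=phase,
        fold_label=f"{coord}.{phase}",
    )


def label_gene_introns(
    gene_model: GeneModel, fold_mapping: FoldMapping
) -> list[IntronSite]:
    """All intron sites of one gene model, labeled on the fold."""
    return [
        label_intron(off, fold_mapping, gene_id=gene_model.gene_id)
        for off in extract_intron_offsets(gene_model)
    ]


def classify_intron_sites(
    sites: list[IntronSite], globin_class: str
) -> list[IntronSite]:
    """Mark each site ancestral or variant for the given globin class.

    B12.2 and G7.0 are ancestral in every class; E10.2 is additionally
    ancestral for GbX.  Everything else is a variant position.
    """
    if globin_class not in GLOBIN_CLASSES:
        raise ValueError(
            f"unknown globin class {globin_class!r}; expected one of {GLOBIN_CLASSES}"
        )
    ancestral = ANCESTRAL_LABELS | CLASS_ANCESTRAL.get(globin_class, frozenset())
    for site in sites:
        site.conservation = "ancestral" if site.fold_label in ancestral else "variant"
    return sites


def summarize_variant_sites(
    sites: list[IntronSite], include_flanking_loops: bool = False
) -> IntronSummary:
    """Count distinct variant intron positions, overall and per fold segment.

    Each variant label is counted once across the whole dataset regardless
    of how many genes carry it.  "In or between helices E and F" means
    segments {E, EF, F}; ``include_flanking_loops`` widens the rule to also
    count the DE and FG loops.
    """
    variant_labels = sorted({s.fold_label for s in sites if s.conservation == "variant"})
    seg_counts: Counter[str] = Counter()
    for label in variant_labels:
        seg_counts[FoldCoordinate.parse(label.rsplit(".", 1)[0]).segment] += 1
    ef = EF_SEGMENTS_WIDE if include_flanking_loops else EF_SEGMENTS
    return IntronSummary(
        per_segment=dict(seg_counts),
        total_variant_sites=len(variant_labels),
        in_or_between_e_f=sum(n for seg, n in seg_counts.items() if seg in ef),
        variant_labels=variant_labels,
    )


def intron_sites_table(sites: list[IntronSite]):
    """Tabulate labeled sites as a DataFrame (gene_id, cds_offset, label, ...)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "gene_id": [s.gene_id for s in sites],
            "cds_offset": [s.cds_offset for s in sites],
            "residue_index": [s.residue_index for s in sites],
            "phase": [s.phase for s in sites],
            "label": [s.fold_label for s in sites],
            "conservation": [s.conservation for s in sites],
        }
    )
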