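"""Readers, writers and column utilities for the formats the pipeline touches.

Protein FASTA (plain and aligned) goes through Biopython; GFF3 gene models
through gffutils.  GFF3 coordinates are 1-based inclusive on disk; every
conversion to 0-based half-open happens inside the consuming code, never here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

logger = logging.getLogger(__name__)

#: the 20 standard amino acids plus ambiguity 'X' and the gap symbol
AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY") | {"X", "-"}


@dataclass
class SequenceRecord:
    """A protein sequence, possibly gapped when taken from an alignment."""

    id: str
    description: str = ""
    residues: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        bad = set(self.residues) - AA_ALPHABET
        if bad & {"U", "O", "u", "o"}:
            raise ValueError(
                f"sequence {self.id!r} contains selenocysteine/pyrrolysine "
                f"({sorted(bad & {'U', 'O', 'u', 'o'})}); not covered by BLOSUM62"
            )
        if bad:
            raise ValueError(f"sequence {self.id!r} contains invalid symbols: {sorted(bad)}")

    @property
    def ungapped(self) -> str:
        return self.residues.replace("-", "")


@dataclass
class Alignment:
    """An ordered stack of equal-length gapped sequences."""

    records: list[SequenceRecord]

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("alignment must contain at least one record")
        lengths = {len(r.residues) for r in self.records}
        if len(lengths) != 1:
            raise ValueError(f"alignment rows have unequal lengths: {sorted(lengths)}")
        if self.n_columns < 1:
            raise ValueError("alignment must have at least one column")
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate sequence ids in alignment: {dupes}")

    @property
    def n_columns(self) -> int:
        return len(self.records[0].residues)

    def __len__(self) -> int:
        return len(self.records)

    def get(self, seq_id: str) -> SequenceRecord:
        for r in self.records:
            if r.id == seq_id:
                return r
        raise KeyError(f"sequence {seq_id!r} not in alignment")

    def column(self, i: int) -> str:
        return "".join(r.residues[i] for r in self.records)


@dataclass
class GeneModel:
    """A protein-coding gene model: its CDS exons on one strand of one region.

    ``cds_exons`` are (start, end) pairs, 1-based inclusive genomic
    coordinates, sorted by genomic start.  On the '-' strand translation
    order is by descending genomic coordinate.
    """

    gene_id: str
    seq_region: str
    strand: str
    cds_exons: list[tuple[int, int]] = field(default_factory=list)
    coding_sequence: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-', got {self.strand!r}")
        self.cds_exons = sorted(self.cds_exons)
        prev_end = 0
        for start, end in self.cds_exons:
            if end < start:
                raise ValueError(f"gene {self.gene_id}: zero/negative-length exon ({start}, {end})")
            if start <= prev_end:
                raise ValueError(f"gene {self.gene_id}: overlapping CDS exons")
            prev_end = end

    @property
    def coding_length(self) -> int:
        return sum(end - start + 1 for start, end in self.cds_exons)

    @property
    def exons_in_translation_order(self) -> list[tuple[int, int]]:
        if self.strand == "+":
            return list(self.cds_exons)
        return list(reversed(self.cds_exons))


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a protein FASTA file, preserving record order and descriptions.

    Sequences are upper-cased; trailing '*' stop symbols are stripped with a
    logged note.  Duplicate ids and empty files raise ``ValueError``.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id in {path}: {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if "*" in seq:
            logger.info("stripping %d stop symbol(s) from %s", seq.count("*"), rec.id)
            seq = seq.replace("*", "")
        desc = rec.description[len(rec.id):].strip() if rec.description.startswith(rec.id) else rec.description
        records.append(SequenceRecord(id=rec.id, description=desc, residues=seq))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 60) -> None:
    bio = [
        _BioRecord(Seq(r.residues), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


def read_alignment(path: str | Path) -> Alignment:
    """Read an aligned FASTA file into an :class:`Alignment`."""
    return Alignment(read_fasta(path))


def write_alignment(alignment: Alignment, path: str | Path, width: int = 60) -> None:
    write_fasta(alignment.records, path, width=width)


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Read gene models from GFF3, grouping CDS features by their parent.

    Each CDS feature must carry a ``Parent`` (or ``gene_id``) attribute; the
    shared value defines the gene.  Mixed strands within one gene are an
    error.  Coordinates stay 1-based inclusive, verbatim from the file.
    """
    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    groups: dict[str, dict] = {}
    order: list[str] = []
    for feat in db.features_of_type("CDS", order_by="start"):
        parents = feat.attributes.get("Parent") or feat.attributes.get("gene_id")
        if not parents:
            raise ValueError(
                f"CDS feature at {feat.seqid}:{feat.start}-{feat.end} has no Parent attribute"
            )
        gid = parents[0]
        if gid not in groups:
            groups[gid] = {"seq_region": feat.seqid, "strand": feat.strand, "exons": []}
            order.append(gid)
        g = groups[gid]
        if feat.strand != g["strand"]:
            raise ValueError(f"gene {gid!r}: CDS features on mixed strands")
        g["exons"].append((feat.start, feat.end))
    if not groups:
        raise ValueError(f"no CDS features found in {path}")
    return [
        GeneModel(gene_id=gid, seq_region=g["seq_region"], strand=g["strand"],
                  cds_exons=g["exons"])
        for gid, g in ((gid, groups[gid]) for gid in order)
    ]


def write_gene_models(models: Sequence[GeneModel], path: str | Path,
                      source: str = "globinkit") -> None:
    """Write gene models as GFF3 CDS features (1-based inclusive, verbatim)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            for start, end in m.cds_exons:
                fh.write(
                    f"{m.seq_region}\t{source}\tCDS\t{start}\t{end}\t.\t{m.strand}\t.\t"
                    f"Parent={m.gene_id}\n"
                )


def read_column_scores(path: str | Path) -> list[float]:
    """Read per-column alignment confidence scores from a one-column TSV.

    Accepts either a headerless column of scores or a TSV with a ``score``
    column (an optional ``column`` index column is ignored).
    """
    df = pd.read_csv(path, sep="\t")
    if "score" in df.columns:
        scores = df["score"].astype(float).tolist()
    else:
        # headerless: first row was consumed as header; re-read
        df = pd.read_csv(path, sep="\t", header=None)
        scores = df.iloc[:, -1].astype(float).tolist()
    bad = [s for s in scores if not (0.0 <= s <= 1.0)]
    if bad:
        raise ValueError(f"column scores outside [0, 1]: {bad[:5]}")
    return scores


def write_column_scores(scores: Sequence[float], path: str | Path) -> None:
    pd.DataFrame({"column": range(1, len(scores) + 1), "score": list(scores)}).to_csv(
        path, sep="\t", index=False
    )


def read_class_labels(path: str | Path) -> dict[str, str]:
    """Read per-sequence class labels (sequence_id, class) from TSV."""
    df = pd.read_csv(path, sep="\t")
    if not {"sequence_id", "class"} <= set(df.columns):
        df = pd.read_csv(path, sep="\t", header=None, names=["sequence_id", "class"])
    return dict(zip(df["sequence_id"].astype(str), df["class"].astype(str)))


def write_class_labels(labels: dict[str, str], path: str | Path) -> None:
    pd.DataFrame(
        {"sequence_id": list(labels), "class": [labels[k] for k in labels]}
    ).to_csv(path, sep="\t", index=False)


def filter_alignment_columns(
    alignment: Alignment, column_scores: Sequence[float], threshold: float = 0.93
) -> Alignment:
    """Keep exactly the columns whose confidence score is >= ``threshold``.

    This is the masking step applied to alignments scored per column by a
    reliability tool: low-confidence columns (score below the cutoff,
    conventionally 0.93) are removed before downstream statistics.
    """
    if len(column_scores) != alignment.n_columns:
        raise ValueError(
            f"score length {len(column_scores)} != alignment columns {alignment.n_columns}"
        )
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    keep = [i for i, s in enumerate(column_scores) if s >= threshold]
    if not keep:
        raise ValueError("no columns meet the threshold; refusing to return an empty alignment")
    records = [
        SequenceRecord(
            id=r.id, description=r.description,
            residues="".join(r.residues[i] for i in keep),
        )
        for r in alignment.records
    ]
    return Alignment(records)
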