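"""Synthetic data with the statistical structure every pipeline stage assumes.

The generator emulates a curated globin-family dataset: three globin
classes (HbL, GbX, GbXL) at controlled within-class pairwise identity,
N-terminal extensions of controlled length, planted key-residue deviants,
planted N-terminal acylation motifs, gene models with introns planted at
declared fold coordinates on either strand, qPCR dilution/sample tables
obeying a linear Ct-log10(copies) law, and Poisson count matrices with
known per-library fold changes.  Every generator is deterministic under a
fixed seed, and each emits a truth table sufficient to score the
downstream module without external data.

Sequence evolution is a simple per-site substitution model: members of a
class derive independently from a class ancestor, each site replaced with
probability q by a BLOSUM62-weighted alternative; q is solved numerically
so the expected pairwise identity between members hits the configured
target.  No phylogeny is simulated — the model provides controlled
divergence, not realistic tree structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from . import seqio
from .acylation import MYR_ALLOWED_P6, MYR_EXCLUDED_P3
from .consstats import blosum62
from .foldmap import (
    FoldCoordinate,
    FoldMapping,
    ReferenceFold,
    build_fold_mapping,
    default_reference_fold,
    default_reference_sequence,
    write_reference_fold,
)
from .seqio import Alignment, GeneModel, SequenceRecord

_AA20 = "ACDEFGHIKLMNPQRSTVWY"
_KEY_CANONICAL = {"CD1": "F", "E7": "H", "F8": "H"}

#: one common codon per amino acid; introns only care about codon boundaries
CODON_TABLE = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT",
    "G": "GGT", "H": "CAT", "I": "ATT", "K": "AAA", "L": "TTA",
    "M": "ATG", "N": "AAT", "P": "CCA", "Q": "CAA", "R": "CGT",
    "S": "TCT", "T": "ACT", "V": "GTT", "W": "TGG", "Y": "TAT",
}

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass
class ClassConfig:
    """Generation plan for one globin class."""

    n: int
    identity: float
    nt_length: int = 0
    myristoyl_fraction: float = 0.0
    palmitoyl_fraction: float = 0.0
    #: member index -> {fold label: residue}, e.g. {0: {"E7": "Q"}}
    deviants: dict[int, dict[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("class size must be >= 1")
        if not 0.0 < self.identity <= 1.0:
            raise ValueError(f"target identity must be in (0, 1], got {self.identity}")
        if (self.myristoyl_fraction or self.palmitoyl_fraction) and self.nt_length < 7:
            raise ValueError("acylation motifs need an N-terminal extension of >= 7 residues")


@dataclass
class FamilyConfig:
    classes: dict[str, ClassConfig]
    seed: int = 0


@dataclass
class SimulatedFamily:
    """A generated globin family with its ground truth."""

    alignment: Alignment           # includes the annotated reference row
    records: list[SequenceRecord]  # ungapped proteins, reference excluded
    class_labels: dict[str, str]
    truth: pd.DataFrame
    reference_fold: ReferenceFold

    def fold_mappings(self) -> dict[str, FoldMapping]:
        return build_fold_mapping(self.alignment, self.reference_fold)

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "proteins": outdir / "proteins.fasta",
            "alignment": outdir / "alignment.fasta",
            "classes": outdir / "classes.tsv",
            "fold": outdir / "fold.tsv",
            "truth": outdir / "truth.tsv",
        }
        seqio.write_fasta(self.records, paths["proteins"])
        seqio.write_alignment(self.alignment, paths["alignment"])
        seqio.write_class_labels(self.class_labels, paths["classes"])
        write_reference_fold(self.reference_fold, paths["fold"])
        self.truth.to_csv(paths["truth"], sep="\t", index=False)
        return paths


def _replacement_weights():
    """For each amino acid, BLOSUM62-softmax weights over the other 19."""
    matrix = blosum62()
    weights = {}
    for a in _AA20:
        others = [b for b in _AA20 if b != a]
        w = np.array([np.exp(matrix[a, b] / 2.0) for b in others])
        weights[a] = (others, w / w.sum())
    return weights


_WEIGHTS = _replacement_weights()


def _solve_mutation_rate(ancestor: str, target_identity: float) -> float:
    """Per-site substitution probability q so that two independent
    descendants of ``ancestor`` have expected pairwise identity ~ target."""
    coincide = np.array([
        float(np.sum(_WEIGHTS[a][1] ** 2)) for a in ancestor
    ])

    def expected_identity(q: float) -> float:
        return float(np.mean((1 - q) ** 2 + q ** 2 * coincide))

    floor = expected_identity(1.0)
    if target_identity >= 1.0:
        return 0.0
    if target_identity <= floor:
        raise ValueError(
            f"target identity {target_identity:.2f} below the model floor {floor:.2f}"
        )
    return brentq(lambda q: expected_identity(q) - target_identity, 0.0, 1.0)


def _mutate(ancestor: str, q: float, rng: np.random.Generator) -> str:
    out = list(ancestor)
    hits = np.nonzero(rng.random(len(out)) < q)[0]
    for i in hits:
        others, w = _WEIGHTS[out[i]]
        out[i] = others[rng.choice(len(others), p=w)]
    return "".join(out)


def _random_protein(n: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list(_AA20), size=n))


def _nterm_with_motifs(
    length: int, myristoyl: bool, palmitoyl: bool, rng: np.random.Generator
) -> str:
    """An N-terminal extension, pattern-conformant or pattern-breaking.

    Myristoylation-positive termini satisfy the six-position pattern after
    the initiator Met; palmitoylation-positive ones carry a Cys at position
    3 (inside the default window), negatives carry no Cys in the first 10
    residues.
    """
    tail = list(_random_protein(max(0, length - 7), rng))
    if myristoyl:
        p3 = "C" if palmitoyl else rng.choice(
            [a for a in _AA20 if a not in MYR_EXCLUDED_P3 and a != "C"]
        )
        p6 = rng.choice([a for a in sorted(MYR_ALLOWED_P6) if palmitoyl or a != "C"])
        p7 = rng.choice([a for a in _AA20 if a != "P" and (palmitoyl or a != "C")])
        p45 = [rng.choice([a for a in _AA20 if palmitoyl or a != "C"]) for _ in range(2)]
        head = ["M", "G", p3, *p45, p6, p7]
    else:
        # breaking the Gly anchor suffices; keep Cys consistent with the plan
        p2 = rng.choice([a for a in _AA20 if a not in {"G", "C"}])
        rest = [
            ("C" if (palmitoyl and i == 0) else
             rng.choice([a for a in _AA20 if palmitoyl or a != "C"]))
            for i in range(5)
        ]
        head = ["M", p2, *rest]
    if not palmitoyl:
        tail[: 10 - 7] = [
            a if a != "C" else "A" for a in tail[: 10 - 7]
        ]
    return "".join(head + tail)[:length]


def simulate_family(config: FamilyConfig) -> SimulatedFamily:
    """Generate a globin family per ``config`` (see module docstring).

    The alignment stacks every member's core against the shared reference
    core; N-terminal extensions occupy left-padded columns where the
    reference is gapped, so they map to segment NT downstream.
    """
    rng = np.random.default_rng(config.seed)
    fold = default_reference_fold()
    ref = default_reference_sequence()
    core_len = len(ref.residues)
    key_res = {
        label: fold.residue_of(FoldCoordinate.parse(label)) for label in _KEY_CANONICAL
    }

    max_nt = max((c.nt_length for c in config.classes.values()), default=0)
    gapped_rows: list[SequenceRecord] = [
        SequenceRecord(id=ref.id, description=ref.description,
                       residues="-" * max_nt + ref.residues)
    ]
    records: list[SequenceRecord] = []
    class_labels: dict[str, str] = {}
    truth_rows: list[dict] = []

    for cls in sorted(config.classes):
        cc = config.classes[cls]
        # class ancestor: a diverged copy of the reference with canonical triad
        ancestor = list(_mutate(ref.residues, 0.35, rng))
        for label, res in key_res.items():
            ancestor[res - 1] = _KEY_CANONICAL[label]
        ancestor = "".join(ancestor)
        # correct the target for the three forced-canonical sites, which
        # match between members regardless of q
        n_keys = len(key_res)
        adj_target = (cc.identity * core_len - n_keys) / (core_len - n_keys)
        q = _solve_mutation_rate(ancestor, adj_target)

        n_myr = int(round(cc.myristoyl_fraction * cc.n))
        n_palm = int(round(cc.palmitoyl_fraction * cc.n))
        for j in range(cc.n):
            seq_id = f"{cls}_{j + 1:03d}"
            core = list(_mutate(ancestor, q, rng))
            for label, res in key_res.items():
                core[res - 1] = _KEY_CANONICAL[label]
            planted = cc.deviants.get(j, {})
            for label, aa in planted.items():
                core[fold.residue_of(FoldCoordinate.parse(label)) - 1] = aa
            core = "".join(core)
            myr = j < n_myr
            palm = j < n_palm
            nterm = (
                _nterm_with_motifs(cc.nt_length, myr, palm, rng)
                if cc.nt_length > 0 else ""
            )
            full = nterm + core
            records.append(SequenceRecord(id=seq_id, description=f"synthetic {cls}",
                                          residues=full))
            gapped_rows.append(
                SequenceRecord(
                    id=seq_id, description=f"synthetic {cls}",
                    residues="-" * (max_nt - cc.nt_length) + full,
                )
            )
            class_labels[seq_id] = cls
            truth_rows.append(
                {
                    "sequence_id": seq_id,
                    "class": cls,
                    "nt_length": cc.nt_length,
                    "target_identity": cc.identity,
                    "myristoylation": myr,
                    "palmitoylation": palm,
                    "deviant": bool(planted),
                    "deviant_detail": ";".join(f"{k}={v}" for k, v in sorted(planted.items())),
                }
            )

    return SimulatedFamily(
        alignment=Alignment(gapped_rows),
        records=records,
        class_labels=class_labels,
        truth=pd.DataFrame(truth_rows),
        reference_fold=fold,
    )


def default_family_config(seed: int = 0) -> FamilyConfig:
    """The shipped study-shaped dataset: 187 globins in three classes.

    Class sizes, identity targets, N-terminal extension lengths and the 14
    planted key-residue deviants follow the composition reported for
    arthropod globin surveys: HbL diverse (identity ~25%, mean length
    ~171 aa), GbX and GbXL conserved (~68%/~67%, ~228/~199 aa) with long
    N-terminal extensions; all deviants sit in HbL, including one triple
    mutant (Met-CD1/Val-E7/Val-F8) and several E7/F8 substitutions.
    """
    hbl_deviants: dict[int, dict[str, str]] = {
        0: {"E7": "Q"}, 1: {"E7": "Q"}, 2: {"E7": "Q"}, 3: {"E7": "Q"},
        4: {"E7": "Q"},
        5: {"E7": "S"}, 6: {"E7": "A"}, 7: {"E7": "R"}, 8: {"E7": "L"},
        9: {"F8": "Y"}, 10: {"F8": "Y"}, 11: {"F8": "Y"}, 12: {"F8": "V"},
        13: {"CD1": "M", "E7": "V", "F8": "V"},
    }
    return FamilyConfig(
        classes={
            "HbL": ClassConfig(n=120, identity=0.25, nt_length=16,
                               myristoyl_fraction=0.5, deviants=hbl_deviants),
            "GbX": ClassConfig(n=30, identity=0.68, nt_length=73,
                               myristoyl_fraction=1.0, palmitoyl_fraction=0.0),
            "GbXL": ClassConfig(n=37, identity=0.67, nt_length=44,
                                myristoyl_fraction=1.0, palmitoyl_fraction=1.0),
        },
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Gene models with planted introns


@dataclass
class SimulatedGene:
    gene_model: GeneModel
    genomic_sequence: str
    planted_labels: list[str]


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def back_translate(protein: str) -> str:
    """Protein -> CDS using one fixed codon per amino acid."""
    try:
        return "".join(CODON_TABLE[aa] for aa in protein)
    except KeyError as exc:
        raise ValueError(f"cannot back-translate residue {exc}") from None


def _offset_for_label(label: str, mapping: FoldMapping) -> int:
    coord_str, _, phase_str = label.rpartition(".")
    phase = int(phase_str)
    if phase not in {0, 1, 2}:
        raise ValueError(f"bad phase in label {label!r}")
    coord = FoldCoordinate.parse(coord_str)
    residues = mapping.residues_of_coordinate(coord)
    if not residues:
        raise ValueError(
            f"label {label!r} outside the fold mapping of {mapping.sequence_id!r}"
        )
    res = residues[0]
    offset = (res - 1) * 3 + phase
    n = len(mapping)
    if not 1 <= offset <= 3 * n - 1:
        raise ValueError(f"label {label!r} yields invalid cds_offset {offset}")
    return offset


def simulate_gene_models(
    proteins: list[SequenceRecord],
    fold_mappings: dict[str, FoldMapping],
    intron_plans: dict[str, list[str]],
    seed: int = 0,
    strands: dict[str, str] | None = None,
) -> list[SimulatedGene]:
    """Back-translate proteins and split the CDS at planted intron labels.

    For each protein, the planned fold labels (e.g. ["B12.2", "G7.0"]) are
    converted to CDS offsets through the protein's fold mapping; the CDS is
    split there and short GT..AG introns inserted.  Minus-strand genes are
    emitted as the reverse complement with mirrored exon coordinates, so
    extraction + labeling must recover the plan on either strand.
    """
    rng = np.random.default_rng(seed)
    strands = strands or {}
    genes: list[SimulatedGene] = []
    for rec in proteins:
        plan = intron_plans.get(rec.id, [])
        mapping = fold_mappings[rec.id]
        offsets = sorted({_offset_for_label(lab, mapping) for lab in plan})
        if len(offsets) != len(plan):
            raise ValueError(f"{rec.id}: duplicate planted intron offsets")
        cds = back_translate(rec.ungapped)
        strand = strands.get(rec.id, "+")
        pieces = []
        prev = 0
        for off in offsets:
            pieces.append(cds[prev:off])
            prev = off
        pieces.append(cds[prev:])
        intron_seqs = [
            "GT" + "".join(rng.choice(list("ACGT"), size=26)) + "AG"
            for _ in offsets
        ]
        genomic = pieces[0]
        exons_plus = [(1, len(pieces[0]))]
        for piece, intron in zip(pieces[1:], intron_seqs):
            genomic += intron
            start = len(genomic) + 1
            genomic += piece
            exons_plus.append((start, start + len(piece) - 1))
        if strand == "-":
            total = len(genomic)
            genomic = _revcomp(genomic)
            exons = sorted((total - e + 1, total - s + 1) for s, e in exons_plus)
        else:
            exons = exons_plus
        genes.append(
            SimulatedGene(
                gene_model=GeneModel(
                    gene_id=rec.id, seq_region=f"scaf_{rec.id}", strand=strand,
                    cds_exons=exons, coding_sequence=cds,
                ),
                genomic_sequence=genomic,
                planted_labels=sorted(plan),
            )
        )
    return genes


def write_simulated_genes(genes: list[SimulatedGene], gff_path: str | Path) -> None:
    seqio.write_gene_models([g.gene_model for g in genes], gff_path)


# ---------------------------------------------------------------------------
# qPCR and count-matrix generators


def simulate_qpcr(
    slope: float = -3.45,
    intercept: float = 38.0,
    tissue_mean_copies: dict[str, float] | None = None,
    n_replicates: int = 3,
    sigma: float = 0.2,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Dilution-series and tissue-sample Ct tables under a linear Ct law.

    Ct = intercept + slope * log10(copies) + N(0, sigma).  The dilution
    series covers 10^7..10^1 copies in 10-fold steps; each tissue sample is
    measured in ``n_replicates`` technical replicates.  Default tissue
    means model brain-dominant expression of a neural globin.
    """
    if sigma < 0:
        raise ValueError("noise sigma must be >= 0")
    if tissue_mean_copies is None:
        tissue_mean_copies = {
            "brain": 1e5, "fat_body": 2e4, "gut": 1e4,
            "malpighian_tubules": 8e3, "salivary_glands": 5e3,
        }
    if any(c <= 0 for c in tissue_mean_copies.values()):
        raise ValueError("tissue mean copies must be positive")
    rng = np.random.default_rng(seed)
    copies = 10.0 ** np.arange(7, 0, -1)
    dilution = pd.DataFrame(
        {
            "copies": copies,
            "ct": intercept + slope * np.log10(copies)
                  + rng.normal(0.0, sigma, size=len(copies)),
        }
    )
    rows = []
    for tissue, mean in tissue_mean_copies.items():
        base_ct = intercept + slope * np.log10(mean)
        for rep in range(1, n_replicates + 1):
            rows.append(
                {
                    "tissue": tissue,
                    "replicate": rep,
                    "ct": base_ct + rng.normal(0.0, sigma),
                }
            )
    return dilution, pd.DataFrame(rows)


def simulate_counts(
    n_genes: int = 200,
    library_sizes: dict[str, int] | None = None,
    n_de_genes: int = 0,
    fold_change: float = 1.0,
    de_libraries: list[str] | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series, list[str]]:
    """Poisson count matrix with known per-library fold changes.

    Baseline per-gene relative abundances f_j are log-normal; counts are
    x_ij ~ Poisson(N_i * f_j * fc_ij), with fc_ij = ``fold_change`` for the
    first ``n_de_genes`` genes in ``de_libraries`` (default: the last
    library) and 1 elsewhere.  Returns (counts genes x libraries,
    library sizes, names of the planted genes).
    """
    if library_sizes is None:
        library_sizes = {"lib_1": 1_000_000, "lib_2": 1_000_000}
    if any(n <= 0 for n in library_sizes.values()):
        raise ValueError("library sizes must be positive")
    rng = np.random.default_rng(seed)
    libs = list(library_sizes)
    if de_libraries is None:
        de_libraries = [libs[-1]]
    unknown = set(de_libraries) - set(libs)
    if unknown:
        raise ValueError(f"unknown DE libraries: {sorted(unknown)}")
    genes = [f"gene_{i + 1:04d}" for i in range(n_genes)]
    planted = genes[:n_de_genes]
    f = 1e-4 * rng.lognormal(0.0, 0.5, size=n_genes)
    counts = {}
    for lib in libs:
        lam = library_sizes[lib] * f
        if lib in de_libraries and n_de_genes:
            lam = lam.copy()
            lam[:n_de_genes] *= fold_change
        counts[lib] = rng.poisson(lam)
    matrix = pd.DataFrame(counts, index=pd.Index(genes, name="gene"))
    sizes = pd.Series(library_sizes, name="library_size")
    return matrix, sizes, planted
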