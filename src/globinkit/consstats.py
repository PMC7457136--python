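"""Per-class conservation and length statistics over an aligned dataset.

Pairwise percent identity and percent similarity are computed over the
"globin core" — the alignment columns spanned by the reference fold from
the first helix-A column through the last helix-H column — under pairwise
deletion (columns where either row is gapped are excluded from the
denominator).  Similarity follows the BLAST-style convention: a residue
pair is similar when its BLOSUM62 score is strictly positive (identical
residues are always counted as similar, so similarity >= identity holds
even for ambiguous 'X' pairs, whose BLOSUM62 diagonal entry is negative).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from Bio.Align import substitution_matrices

from .foldmap import ReferenceFold, build_fold_mapping, key_position_column, nterm_extension_length
from .seqio import Alignment


def blosum62():
    """The BLOSUM62 substitution matrix (symmetric, integer log-odds)."""
    return substitution_matrices.load("BLOSUM62")


@dataclass
class ClassConservation:
    globin_class: str
    n_sequences: int
    mean_identity_pct: float
    mean_similarity_pct: float
    mean_length_aa: float
    mean_nt_extension_aa: float


def core_columns(alignment: Alignment, reference_fold: ReferenceFold) -> list[int]:
    """Alignment columns of the globin core: first helix-A reference column
    through the last helix-H reference column, inclusive of internal loops."""
    a_start, _ = reference_fold.segment_span("A")
    _, h_end = reference_fold.segment_span("H")
    first = None
    last = None
    ref = alignment.get(reference_fold.reference_id)
    ri = 0
    for col, ch in enumerate(ref.residues):
        if ch != "-":
            ri += 1
            if ri == a_start:
                first = col
            if ri == h_end:
                last = col
                break
    if first is None or last is None:
        raise ValueError("reference does not span helices A..H in the alignment")
    return list(range(first, last + 1))


def pairwise_identity_similarity(
    row_a: str,
    row_b: str,
    matrix=None,
    core_cols: list[int] | None = None,
) -> tuple[float | None, float | None]:
    """Percent identity and percent similarity between two alignment rows.

    Only columns where both rows are non-gap ("comparable") enter the
    denominator; with zero comparable columns both metrics are undefined
    and reported as None.
    """
    if len(row_a) != len(row_b):
        raise ValueError(f"rows of unequal length: {len(row_a)} vs {len(row_b)}")
    if matrix is None:
        matrix = blosum62()
    cols = range(len(row_a)) if core_cols is None else core_cols
    comparable = matches = similar = 0
    for i in cols:
        a, b = row_a[i], row_b[i]
        if a == "-" or b == "-":
            continue
        comparable += 1
        if a == b:
            matches += 1
            similar += 1
        elif matrix[a, b] > 0:
            similar += 1
    if comparable == 0:
        return None, None
    return 100.0 * matches / comparable, 100.0 * similar / comparable


def class_conservation_summary(
    alignment: Alignment,
    class_labels: dict[str, str],
    reference_fold: ReferenceFold,
    matrix=None,
) -> pd.DataFrame:
    """Mean pairwise identity/similarity and length statistics per class.

    Averages run over all unordered within-class pairs on the globin core;
    mean protein length is over ungapped full sequences and the mean
    N-terminal extension comes from the fold mapping.  Classes with fewer
    than two labeled members are omitted with a warning.
    """
    if matrix is None:
        matrix = blosum62()
    cols = core_columns(alignment, reference_fold)
    mappings = build_fold_mapping(alignment, reference_fold)
    by_class: dict[str, list] = {}
    for rec in alignment.records:
        cls = class_labels.get(rec.id)
        if cls is not None:
            by_class.setdefault(cls, []).append(rec)
    rows = []
    for cls in sorted(by_class):
        members = by_class[cls]
        if len(members) < 2:
            warnings.warn(
                f"class {cls!r} has {len(members)} labeled member(s); omitted from summary"
            )
            continue
        idents, sims = [], []
        for a, b in combinations(members, 2):
            ident, sim = pairwise_identity_similarity(
                a.residues, b.residues, matrix=matrix, core_cols=cols
            )
            if ident is not None:
                idents.append(ident)
                sims.append(sim)
        rows.append(
            ClassConservation(
                globin_class=cls,
                n_sequences=len(members),
                mean_identity_pct=float(np.mean(idents)) if idents else float("nan"),
                mean_similarity_pct=float(np.mean(sims)) if sims else float("nan"),
                mean_length_aa=float(np.mean([len(m.ungapped) for m in members])),
                mean_nt_extension_aa=float(
                    np.mean([nterm_extension_length(mappings[m.id]) for m in members])
                ),
            )
        )
    return pd.DataFrame([vars(r) for r in rows])
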