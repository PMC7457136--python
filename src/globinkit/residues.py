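"""Survey of the three heme/ligand-critical globin residues.

Classical globins conserve a phenylalanine at CD1 (first position of the
loop between helices C and D) and two histidines: the distal His at E7 and
the proximal, iron-coordinating His at F8.  This module reads the residues
at those three fold positions for every sequence in an alignment and
aggregates how many sequences retain the full canonical triad.
"""

from __future__ import annotations

from dataclasses import dataclass

from .foldmap import ReferenceFold, key_position_column
from .seqio import Alignment

KEY_LABELS = ("CD1", "E7", "F8")
CANONICAL = {"CD1": "F", "E7": "H", "F8": "H"}
#: Gln at the distal E7 position is a functionally conservative replacement
CONSERVATIVE = {"E7": {"Q"}}


@dataclass
class KeyResidueReport:
    """Residues and verdicts at CD1/E7/F8 for one sequence."""

    sequence_id: str
    residue_at: dict[str, str]
    verdict_at: dict[str, str]
    all_canonical: bool


def _verdict(label: str, residue: str, count_conservative: bool) -> str:
    if residue == "-":
        return "absent"
    if residue == CANONICAL[label]:
        return "canonical"
    if residue in CONSERVATIVE.get(label, set()):
        return "conservative"
    return "deviant"


def survey_key_residues(
    alignment: Alignment,
    reference_fold: ReferenceFold,
    count_conservative: bool = False,
    sequence_ids: list[str] | None = None,
) -> tuple[list[KeyResidueReport], int]:
    """Per-sequence key-residue reports plus the all-canonical count.

    ``all_canonical`` requires the strict F/H/H triad by default; with
    ``count_conservative`` the functionally conservative Gln at E7 also
    counts.  A gap at a key column reports "absent" and never counts as
    canonical.  Returns (reports, number of sequences with the full triad).
    ``sequence_ids`` restricts the survey to a subset (e.g. to exclude the
    annotation scaffold itself from dataset counts); by default every row,
    including the reference, is surveyed.
    """
    columns = {
        label: key_position_column(reference_fold, alignment, label)
        for label in KEY_LABELS
    }
    wanted = None if sequence_ids is None else set(sequence_ids)
    reports: list[KeyResidueReport] = []
    aggregate = 0
    for rec in alignment.records:
        if wanted is not None and rec.id not in wanted:
            continue
        residue_at = {label: rec.residues[col] for label, col in columns.items()}
        verdict_at = {
            label: _verdict(label, residue_at[label], count_conservative)
            for label in KEY_LABELS
        }
        ok_verdicts = (
            {"canonical", "conservative"} if count_conservative else {"canonical"}
        )
        all_canonical = all(v in ok_verdicts for v in verdict_at.values())
        reports.append(
            KeyResidueReport(
                sequence_id=rec.id,
                residue_at=residue_at,
                verdict_at=verdict_at,
                all_canonical=all_canonical,
            )
        )
        aggregate += all_canonical
    return reports, aggregate


def key_residue_table(reports: list[KeyResidueReport]):
    """Tabulate reports as a DataFrame (sequence_id, CD1, E7, F8, verdicts)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "sequence_id": [r.sequence_id for r in reports],
            **{
                label: [r.residue_at[label] for r in reports]
                for label in KEY_LABELS
            },
            **{
                f"{label}_verdict": [r.verdict_at[label] for r in reports]
                for label in KEY_LABELS
            },
            "all_canonical": [r.all_canonical for r in reports],
        }
    )
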