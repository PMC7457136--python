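"""N-terminal acylation motif scanning and multi-predictor consensus.

N-myristoylation attaches myristate to an N-terminal glycine exposed after
cleavage of the initiator methionine; it is recognized here by the classic
six-position consensus pattern (G at position 2, a non-charged/non-aromatic
residue at 3, any at 4-5, a small residue at 6, no proline at 7).
3C-palmitoylation attaches palmitate to a cysteine near the N-terminus and
frequently pairs with myristoylation to anchor a protein to the membrane;
it is modeled as a cysteine within a configurable N-terminal window.

Because published myristoylation surveys typically vote across several
predictors (pattern-based and learned), the consensus layer accepts
external predictor calls alongside the built-in pattern scan and reports a
vote tier (how many predictors agree).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from .seqio import SequenceRecord

#: excluded at pattern position 3 (after the Gly): charged, aromatic, Pro
MYR_EXCLUDED_P3 = frozenset("EDRKHPFYW")
#: allowed small residues at pattern position 6
MYR_ALLOWED_P6 = frozenset("STAGCN")

DEFAULT_PALM_WINDOW = 10
DEFAULT_CONSENSUS_THRESHOLD = 2


@dataclass
class MotifCall:
    """Combined acylation annotation for one sequence."""

    sequence_id: str
    myristoylation: str  # positive / negative / uncertain
    palmitoylation_sites: list[int] = field(default_factory=list)
    predictor_votes: int = 0
    n_terminus_reliable: bool = True


def scan_myristoylation(sequence: str) -> bool | None:
    """Pattern scan for an N-myristoylation motif.

    Applied after initiator-Met removal: with 1-based numbering on the
    original sequence, returns True iff position 2 is G, position 3 is not
    one of {E,D,R,K,H,P,F,Y,W}, position 6 is one of {S,T,A,G,C,N} and
    position 7 is not P (positions 4 and 5 unconstrained).  Sequences that
    do not start with Met or are shorter than 7 residues cannot be
    evaluated and return None (uncertain).
    """
    seq = sequence.upper()
    if len(seq) < 7 or not seq.startswith("M"):
        return None
    return (
        seq[1] == "G"
        and seq[2] not in MYR_EXCLUDED_P3
        and seq[5] in MYR_ALLOWED_P6
        and seq[6] != "P"
    )


def scan_palmitoylation(sequence: str, window: int = DEFAULT_PALM_WINDOW) -> list[int]:
    """1-based positions of cysteines within the N-terminal window.

    Position 1 (the initiator Met) is never reported; candidates run from
    position 2 through ``window``.
    """
    if window < 1:
        raise ValueError(f"window must be >= 1, got {window}")
    seq = sequence.upper()
    return [i for i in range(2, min(window, len(seq)) + 1) if seq[i - 1] == "C"]


def consensus_call(
    votes: Sequence[bool], threshold: int = DEFAULT_CONSENSUS_THRESHOLD
) -> tuple[int, bool]:
    """Combine predictor votes into a tier and a positive/negative call.

    Returns (tier, positive) where tier is the number of positive votes and
    the call is positive iff tier >= threshold.
    """
    if len(votes) == 0:
        raise ValueError("no predictor votes registered")
    tier = sum(bool(v) for v in votes)
    return tier, tier >= threshold


def call_acylation(
    record: SequenceRecord,
    external_votes: Sequence[bool] = (),
    window: int = DEFAULT_PALM_WINDOW,
    threshold: int = DEFAULT_CONSENSUS_THRESHOLD,
    n_terminus_reliable: bool = True,
) -> MotifCall:
    """Full acylation call for one sequence.

    The built-in pattern scan contributes one vote; ``external_votes`` (e.g.
    imported predictions from learned tools) contribute the rest.  Sequences
    flagged as having an unreliable N-terminus (incomplete gene models) are
    reported uncertain and should be excluded from counts.
    """
    seq = record.ungapped
    own = scan_myristoylation(seq)
    if not n_terminus_reliable or own is None:
        return MotifCall(
            sequence_id=record.id,
            myristoylation="uncertain",
            palmitoylation_sites=[],
            predictor_votes=0,
            n_terminus_reliable=False,
        )
    votes = [own, *external_votes]
    tier, positive = consensus_call(votes, threshold=threshold)
    return MotifCall(
        sequence_id=record.id,
        myristoylation="positive" if positive else "negative",
        palmitoylation_sites=scan_palmitoylation(seq, window=window),
        predictor_votes=tier,
        n_terminus_reliable=True,
    )


def read_external_votes(path: str | Path) -> dict[str, list[bool]]:
    """Read external predictor calls from TSV (sequence_id, predictor, call).

    ``call`` accepts true/false, yes/no, 1/0, positive/negative.
    """
    truthy = {"true", "yes", "1", "positive", "t", "y"}
    falsy = {"false", "no", "0", "negative", "f", "n"}
    df = pd.read_csv(path, sep="\t")
    votes: dict[str, list[bool]] = {}
    for row in df.itertuples():
        call = str(row.call).strip().lower()
        if call in truthy:
            val = True
        elif call in falsy:
            val = False
        else:
            raise ValueError(f"unrecognized call value {row.call!r} for {row.sequence_id}")
        votes.setdefault(str(row.sequence_id), []).append(val)
    return votes


def motif_table(calls: list[MotifCall], class_labels: dict[str, str] | None = None):
    """Tabulate calls as a DataFrame mirroring a per-class annotation figure."""
    rows = []
    for c in calls:
        rows.append(
            {
                "sequence_id": c.sequence_id,
                "class": (class_labels or {}).get(c.sequence_id, ""),
                "myristoylation": c.myristoylation,
                "tier": c.predictor_votes,
                "palmitoylation_sites": ",".join(map(str, c.palmitoylation_sites)),
                "n_terminus_reliable": c.n_terminus_reliable,
            }
        )
    return pd.DataFrame(rows)
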