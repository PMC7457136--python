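"""The globin-fold coordinate system and projection of queries onto it.

The canonical globin fold is a ~140-residue 3-over-3 alpha-helical sandwich
whose eight helices are named A through H; loops are named by their flanking
helices (AB, BC, CD, DE, EF, FG, GH), and sequence outside the fold is NT
(before helix A) or CT (after helix H).  Positions within a segment are
1-based, so "E7" is the seventh residue of helix E and "CD1" the first
residue of the loop between helices C and D.

A :class:`ReferenceFold` annotates one reference sequence with segment
boundaries; any query aligned to that reference in an MSA inherits fold
coordinates column by column.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from .seqio import Alignment, SequenceRecord

HELICES = tuple("ABCDEFGH")
LOOPS = tuple(a + b for a, b in zip(HELICES, HELICES[1:]))
VALID_SEGMENTS = {"NT", "CT", *HELICES, *LOOPS}

#: canonical traversal order of fold segments, N- to C-terminal
SEGMENT_ORDER = ("NT", "A", "AB", "B", "BC", "C", "CD", "D", "DE",
                 "E", "EF", "F", "FG", "G", "GH", "H", "CT")

_COORD_RE = re.compile(r"^(NT|CT|[A-H]{1,2})(\d+)$")


@dataclass(frozen=True, order=False)
class FoldCoordinate:
    """A position on the globin fold, e.g. B12 = 12th residue of helix B."""

    segment: str
    index: int

    def __post_init__(self) -> None:
        if self.segment not in VALID_SEGMENTS:
            raise ValueError(f"unknown fold segment {self.segment!r}")
        if self.index < 1:
            raise ValueError(f"fold index must be >= 1, got {self.index}")

    def __str__(self) -> str:
        return f"{self.segment}{self.index}"

    @classmethod
    def parse(cls, label: str) -> "FoldCoordinate":
        m = _COORD_RE.match(label)
        if not m or m.group(1) not in VALID_SEGMENTS:
            raise ValueError(f"cannot parse fold coordinate {label!r}")
        return cls(m.group(1), int(m.group(2)))


@dataclass
class ReferenceFold:
    """Named fold segments as 1-based inclusive residue ranges on a reference.

    Segments must be unique, non-overlapping and ascending; they need not
    tile the reference — uncovered residues are assigned to the enclosing
    inter-segment region when a mapping is built.
    """

    reference_id: str
    segments: list[tuple[str, int, int]]

    def __post_init__(self) -> None:
        names = [s[0] for s in self.segments]
        if len(set(names)) != len(names):
            raise ValueError("segment names must be unique")
        prev_end = 0
        order_pos = -1
        for name, start, end in self.segments:
            if name not in VALID_SEGMENTS:
                raise ValueError(f"invalid segment name {name!r}")
            if start < 1 or end < start:
                raise ValueError(f"segment {name}: bad range ({start}, {end})")
            if start <= prev_end:
                raise ValueError(f"segment {name}: overlaps/precedes previous segment")
            pos = SEGMENT_ORDER.index(name)
            if pos <= order_pos:
                raise ValueError(f"segment {name}: out of canonical fold order")
            order_pos = pos
            prev_end = end

    def segment_span(self, name: str) -> tuple[int, int]:
        for n, start, end in self.segments:
            if n == name:
                return start, end
        raise KeyError(f"segment {name!r} not in reference fold")

    def residue_of(self, coord: FoldCoordinate) -> int:
        """1-based reference residue holding a declared fold coordinate."""
        start, end = self.segment_span(coord.segment)
        res = start + coord.index - 1
        if res > end:
            raise ValueError(
                f"{coord} exceeds segment {coord.segment} length {end - start + 1}"
            )
        return res

    def max_residue(self) -> int:
        return self.segments[-1][2]

    def residue_coordinates(self, n_residues: int) -> list[FoldCoordinate]:
        """Fold coordinate for every reference residue 1..n_residues.

        Residues outside declared segments get the enclosing inter-segment
        region (NT before the first segment, CT after the last, otherwise
        the loop named by the flanking pair) with indices continuing.
        """
        if n_residues < self.max_residue():
            raise ValueError(
                f"reference has {n_residues} residues but segments extend to "
                f"{self.max_residue()}"
            )
        coords: list[FoldCoordinate] = []
        counters: dict[str, int] = {}
        seg_iter = list(self.segments)
        for res in range(1, n_residues + 1):
            hit = None
            prev_seg = next_seg = None
            for name, start, end in seg_iter:
                if start <= res <= end:
                    hit = (name, res - start + 1)
                    break
                if end < res:
                    prev_seg = name
                if start > res and next_seg is None:
                    next_seg = name
            if hit is not None:
                name, idx = hit
                counters[name] = idx
                coords.append(FoldCoordinate(name, idx))
            else:
                region = insertion_region(prev_seg, next_seg)
                counters[region] = counters.get(region, 0) + 1
                coords.append(FoldCoordinate(region, counters[region]))
        return coords


def insertion_region(prev_seg: str | None, next_seg: str | None) -> str:
    """Region name for residues falling between two fold segments.

    Before the first segment -> NT, after the last -> CT, between two
    occurrences of one segment -> that segment; otherwise the loop named by
    the flanking helix letters (a flanking loop/terminus absorbs the gap).
    """
    if prev_seg is None:
        return "NT"
    if next_seg is None:
        return "CT"
    if prev_seg == next_seg:
        return prev_seg
    if prev_seg == "NT":
        return "NT"
    if next_seg == "CT":
        return "CT"
    # a helix adjacent to its own loop: the loop absorbs the insertion
    if next_seg in LOOPS and next_seg.startswith(prev_seg[-1]):
        return next_seg
    if prev_seg in LOOPS and prev_seg.endswith(next_seg[0]):
        return prev_seg
    cand = prev_seg[-1] + next_seg[0]
    if cand in LOOPS:
        return cand
    return prev_seg


@dataclass
class FoldMapping:
    """Per-residue fold coordinates for one (ungapped) query sequence."""

    sequence_id: str
    coords: list[FoldCoordinate | None] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.coords)

    def coordinate_of(self, residue_index: int) -> FoldCoordinate | None:
        """Fold coordinate of the 1-based ``residue_index``-th residue."""
        if not 1 <= residue_index <= len(self.coords):
            raise IndexError(
                f"residue {residue_index} outside sequence {self.sequence_id!r} "
                f"(length {len(self.coords)})"
            )
        return self.coords[residue_index - 1]

    def residues_of_coordinate(self, coord: FoldCoordinate) -> list[int]:
        return [i + 1 for i, c in enumerate(self.coords) if c == coord]


def _reference_column_coords(
    alignment: Alignment, fold: ReferenceFold
) -> tuple[SequenceRecord, list[FoldCoordinate | None]]:
    """Fold coordinate of the reference residue in each alignment column
    (None where the reference is gapped)."""
    try:
        ref = alignment.get(fold.reference_id)
    except KeyError:
        raise ValueError(
            f"reference {fold.reference_id!r} missing from alignment"
        ) from None
    ref_coords = fold.residue_coordinates(len(ref.ungapped))
    out: list[FoldCoordinate | None] = []
    ri = 0
    for ch in ref.residues:
        if ch == "-":
            out.append(None)
        else:
            out.append(ref_coords[ri])
            ri += 1
    return ref, out


def build_fold_mapping(
    alignment: Alignment, fold: ReferenceFold
) -> dict[str, FoldMapping]:
    """Project every sequence in the alignment onto the fold coordinates.

    Each query residue aligned to a reference residue inherits that
    residue's coordinate.  Query residues in columns where the reference is
    gapped are insertions: inside a segment they continue that segment's
    indices past the last one seen; between segments they take the
    enclosing loop (or NT/CT) with their own running indices.
    """
    _, col_coords = _reference_column_coords(alignment, fold)
    # per column: either the concrete reference coordinate, or the insertion
    # region derived from the nearest flanking reference coordinates
    n_cols = alignment.n_columns
    prev_seg: list[str | None] = [None] * n_cols
    last = None
    for i in range(n_cols):
        prev_seg[i] = last
        if col_coords[i] is not None:
            last = col_coords[i].segment
            prev_seg[i] = None  # unused for concrete columns
    next_seg: list[str | None] = [None] * n_cols
    nxt = None
    for i in range(n_cols - 1, -1, -1):
        next_seg[i] = nxt
        if col_coords[i] is not None:
            nxt = col_coords[i].segment

    mappings: dict[str, FoldMapping] = {}
    for rec in alignment.records:
        coords: list[FoldCoordinate | None] = []
        counters: dict[str, int] = {}
        for i, ch in enumerate(rec.residues):
            if ch == "-":
                continue
            cc = col_coords[i]
            if cc is not None:
                counters[cc.segment] = max(counters.get(cc.segment, 0), cc.index)
                coords.append(cc)
            else:
                region = insertion_region(prev_seg[i], next_seg[i])
                counters[region] = counters.get(region, 0) + 1
                coords.append(FoldCoordinate(region, counters[region]))
        mappings[rec.id] = FoldMapping(sequence_id=rec.id, coords=coords)
    return mappings


def key_position_column(
    fold: ReferenceFold, alignment: Alignment, position_label: str
) -> int:
    """0-based alignment column occupied by a reference fold position.

    ``position_label`` is a fold coordinate such as "CD1", "E7" or "F8";
    it must lie within the declared reference segmentation.
    """
    coord = FoldCoordinate.parse(position_label)
    res = fold.residue_of(coord)  # raises for unknown/out-of-range
    ref = alignment.get(fold.reference_id)
    ri = 0
    for col, ch in enumerate(ref.residues):
        if ch != "-":
            ri += 1
            if ri == res:
                return col
    raise ValueError(
        f"reference {fold.reference_id!r} has fewer than {res} residues in alignment"
    )


def nterm_extension_length(mapping: FoldMapping) -> int:
    """Number of residues N-terminal to the globin core (segment NT)."""
    return sum(1 for c in mapping.coords if c is not None and c.segment == "NT")


def reorder_segments(
    sequence: SequenceRecord,
    segment_spans: dict[str, tuple[int, int]],
    target_order: list[str],
) -> SequenceRecord:
    """Concatenate named subsequences of ``sequence`` in a new order.

    Used to restore the standard A-to-H helix order for proteins whose
    globin domain is internally rearranged (e.g. the degenerate globin
    domain of androglobin).  Spans are 1-based inclusive; residues outside
    every span are dropped.
    """
    spans = sorted(segment_spans.items(), key=lambda kv: kv[1][0])
    prev_end = 0
    for name, (start, end) in spans:
        if start < 1 or end < start or end > len(sequence.residues):
            raise ValueError(f"span {name}: bad range ({start}, {end})")
        if start <= prev_end:
            raise ValueError(f"span {name}: overlaps a previous span")
        prev_end = end
    unknown = set(target_order) - set(segment_spans)
    if unknown:
        raise ValueError(f"unknown span name(s) in target order: {sorted(unknown)}")
    if sorted(target_order) != sorted(segment_spans):
        raise ValueError("target order must be a permutation of the span names")
    parts = []
    for name in target_order:
        start, end = segment_spans[name]
        parts.append(sequence.residues[start - 1:end])
    return SequenceRecord(
        id=sequence.id,
        description=(sequence.description + " reordered").strip(),
        residues="".join(parts),
    )


# ---------------------------------------------------------------------------
# Shipped default reference fold: a synthetic consensus globin fixture with
# declared helix boundaries.  Its boundaries are an artifact convention, not
# a measured structure; callers may supply their own annotation instead.

DEFAULT_SEGMENTS: list[tuple[str, int, int]] = [
    ("A", 1, 16), ("AB", 17, 21), ("B", 22, 37), ("BC", 38, 40),
    ("C", 41, 47), ("CD", 48, 55), ("D", 56, 62), ("DE", 63, 67),
    ("E", 68, 87), ("EF", 88, 95), ("F", 96, 105), ("FG", 106, 110),
    ("G", 111, 129), ("GH", 130, 134), ("H", 135, 155),
]

_AA20 = "ACDEFGHIKLMNPQRSTVWY"
# background composition loosely following globular-protein frequencies
_AA_FREQ = np.array([
    0.074, 0.025, 0.054, 0.054, 0.047, 0.074, 0.026, 0.068, 0.058, 0.099,
    0.025, 0.045, 0.039, 0.034, 0.052, 0.057, 0.051, 0.073, 0.013, 0.032,
])
_AA_FREQ = _AA_FREQ / _AA_FREQ.sum()

#: canonical heme-pocket residues on the default fold
KEY_POSITIONS = {"CD1": "F", "E7": "H", "F8": "H"}


def default_reference_fold(reference_id: str = "REF_globin") -> ReferenceFold:
    """The shipped synthetic consensus-globin segmentation (A1..H21, 155 aa)."""
    return ReferenceFold(reference_id=reference_id, segments=list(DEFAULT_SEGMENTS))


def default_reference_sequence(reference_id: str = "REF_globin") -> SequenceRecord:
    """A deterministic 155-residue synthetic consensus globin carrying the
    canonical PheCD1 / HisE7 / HisF8 triad."""
    rng = np.random.default_rng(185207)
    fold = default_reference_fold(reference_id)
    n = fold.max_residue()
    residues = list(rng.choice(list(_AA20), size=n, p=_AA_FREQ))
    for label, aa in KEY_POSITIONS.items():
        residues[fold.residue_of(FoldCoordinate.parse(label)) - 1] = aa
    return SequenceRecord(id=reference_id, description="synthetic consensus globin",
                          residues="".join(residues))


def read_reference_fold(path, reference_id: str | None = None) -> ReferenceFold:
    """Read a fold annotation TSV (segment, start, end; 1-based inclusive).

    The reference id may be given as a ``# reference=<id>`` header line or
    via ``reference_id``.
    """
    import pandas as pd

    ref_id = reference_id
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#") and "reference=" in first:
        ref_id = first.split("reference=")[1].strip()
    if ref_id is None:
        raise ValueError("reference_id not given and no '# reference=' header found")
    df = pd.read_csv(path, sep="\t", comment="#")
    segs = [(str(r.segment), int(r.start), int(r.end)) for r in df.itertuples()]
    return ReferenceFold(reference_id=ref_id, segments=segs)


def write_reference_fold(fold: ReferenceFold, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# reference={fold.reference_id}\n")
        fh.write("segment\tstart\tend\n")
        for name, start, end in fold.segments:
            fh.write(f"{name}\t{start}\t{end}\n")
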