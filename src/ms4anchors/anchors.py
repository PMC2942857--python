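"""Pairwise anchor segments and aligner-specific anchor file writers.

Anchor-aware aligners consume pairs of matching positions (or segments),
not multi-sequence columns, so a column set is expanded pairwise: for
every pair of sequences, every maximal diagonal run of positions
``(i, p + t) / (i', p' + t)`` such that each offset's pair of sites is
co-member of *some* partial column becomes one anchor segment.
Consecutive pairs of a run may come from different columns.

Three output dialects are provided:

* a DIALIGN 2 anchor file (``seq_a seq_b start_a start_b length weight``,
  1-based, one segment per line);
* a BALLAST-style anchor list for ClustalW / DbClustal (dialect frozen by
  this package, documented in the writer);
* a T-Coffee library file (``TC_LIB_FORMAT_01``), each segment expanded
  into residue-pair constraint lines.

Weights follow the two published schemes: ``length10`` scores a segment
10 * length (ClustalW / DIALIGN), ``tcoffee_uniform`` gives every
constraint the uniform value 100 * M where M is the number of sequences.
All writers are deterministic: identical input gives byte-identical files.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from itertools import combinations, groupby

from .errors import ParameterError
from .ms4 import ColumnSet
from .sitespace import SequenceSet

__all__ = [
    "AnchorSegment",
    "extract_segments",
    "weight_segments",
    "write_dialign_anchors",
    "write_ballast",
    "write_tcoffee_lib",
    "WEIGHT_SCHEMES",
]

WEIGHT_SCHEMES = ("length10", "tcoffee_uniform")


@dataclass(frozen=True)
class AnchorSegment:
    """A maximal diagonal run of column-supported position pairs.

    Coordinates are 0-based internally (``seq_a < seq_b``); every writer
    shifts to 1-based on output.
    """

    seq_a: int
    seq_b: int
    start_a: int
    start_b: int
    length: int
    weight: int | None = None


def extract_segments(cols: ColumnSet) -> list[AnchorSegment]:
    """All maximal segments of consecutive column-co-member site pairs.

    For each unordered sequence pair, collect the position pairs induced
    by the columns touching both sequences, then merge pairs lying on the
    same diagonal at consecutive offsets.  Maximality: a run is emitted
    only from a pair with no diagonal predecessor, and extended as far as
    diagonal successors exist.
    """
    cols.validate_disjoint()
    pair_map: dict[tuple[int, int], set[tuple[int, int]]] = {}
    for col in cols:
        for (sa, pa), (sb, pb) in combinations(col.sites, 2):
            # col.sites is sorted by sequence, so sa < sb
            pair_map.setdefault((sa, sb), set()).add((pa, pb))
    segments: list[AnchorSegment] = []
    for (sa, sb), pairs in pair_map.items():
        for pa, pb in pairs:
            if (pa - 1, pb - 1) in pairs:
                continue  # not the start of a maximal run
            length = 1
            while (pa + length, pb + length) in pairs:
                length += 1
            segments.append(
                AnchorSegment(seq_a=sa, seq_b=sb, start_a=pa, start_b=pb, length=length)
            )
    segments.sort(key=lambda s: (s.seq_a, s.seq_b, s.start_a, s.start_b))
    return segments


def weight_segments(
    segs: list[AnchorSegment], scheme: str, n_seqs: int | None = None
) -> list[AnchorSegment]:
    """Attach weights: ``length10`` -> 10 * length; ``tcoffee_uniform`` ->
    100 * n_seqs for every segment."""
    if scheme == "length10":
        return [replace(s, weight=10 * s.length) for s in segs]
    if scheme == "tcoffee_uniform":
        if n_seqs is None or n_seqs < 1:
            raise ParameterError(
                "tcoffee_uniform weighting needs the sequence count (>= 1)"
            )
        return [replace(s, weight=100 * n_seqs) for s in segs]
    raise ParameterError(
        f"unknown weighting scheme {scheme!r}; choose from {WEIGHT_SCHEMES}"
    )


def _require_weights(segs: list[AnchorSegment]) -> None:
    for s in segs:
        if s.weight is None:
            raise ParameterError("segments must be weighted before writing")


def write_dialign_anchors(
    segs: list[AnchorSegment], seqs: SequenceSet, path
) -> None:
    """DIALIGN 2 anchor file: one line per segment,
    ``seq_a seq_b start_a start_b length weight`` (all 1-based)."""
    _require_weights(segs)
    with open(path, "w") as fh:
        for s in segs:
            fh.write(
                f"{s.seq_a + 1} {s.seq_b + 1} {s.start_a + 1} "
                f"{s.start_b + 1} {s.length} {s.weight}\n"
            )


def write_ballast(segs: list[AnchorSegment], seqs: SequenceSet, path) -> None:
    """BALLAST-style anchor list (fixed dialect of this package).

    Layout: a header line naming the query (first) sequence, then one
    record per segment::

        # BALLAST anchor list
        # query: <first sequence identifier>
        <id_a> <id_b> <start_a> <start_b> <length> <weight>

    Positions are 1-based.  The grammar accepted by DbClustal is not
    publicly specified; this dialect is frozen and versioned so that a
    future fix touches this writer only.
    """
    _require_weights(segs)
    with open(path, "w") as fh:
        fh.write("# BALLAST anchor list\n")
        fh.write(f"# query: {seqs.ids[0]}\n")
        for s in segs:
            fh.write(
                f"{seqs.ids[s.seq_a]} {seqs.ids[s.seq_b]} "
                f"{s.start_a + 1} {s.start_b + 1} {s.length} {s.weight}\n"
            )


def write_tcoffee_lib(segs: list[AnchorSegment], seqs: SequenceSet, path) -> None:
    """T-Coffee library file (TC_LIB_FORMAT_01).

    Header, sequence count, one ``name length residues`` line per
    sequence, then per sequence-pair blocks ``#a b`` (1-based sequence
    numbers) with one ``res_a res_b weight`` line per constrained residue
    pair expanded from the segments, terminated by ``! SEQ_1_TO_N``.
    """
    _require_weights(segs)
    with open(path, "w") as fh:
        fh.write("! TC_LIB_FORMAT_01\n")
        fh.write(f"{seqs.n}\n")
        for ident, residues in seqs:
            fh.write(f"{ident} {len(residues)} {residues}\n")
        keyed = sorted(segs, key=lambda s: (s.seq_a, s.seq_b, s.start_a, s.start_b))
        for (sa, sb), group in groupby(keyed, key=lambda s: (s.seq_a, s.seq_b)):
            fh.write(f"#{sa + 1} {sb + 1}\n")
            for seg in group:
                for t in range(seg.length):
                    fh.write(
                        f"{seg.start_a + t + 1} {seg.start_b + t + 1} {seg.weight}\n"
                    )
        fh.write("! SEQ_1_TO_N\n")
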