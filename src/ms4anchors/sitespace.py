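"""Sequences, sites, and site classes.

A collection of ``n`` unaligned sequences over a finite alphabet induces a
*site space*: the set of all positions ``(i, p)`` with ``0 <= i < n`` and
``0 <= p < len(sequence i)``.  Sites carry a natural partial order: two
sites are comparable only when they lie in the same sequence, and are then
ordered left to right.  Every later stage of the pipeline — word-context
clustering, column selection, consistency filtering — operates on subsets
of this space.

A subset of sites is *ambiguous* when it contains two positions of the same
sequence (an internal repeat); such a subset can never be part of an
alignment column.  Non-ambiguous subsets are the partial alignment columns
that the rest of the package selects, filters, and exports.

Internally all coordinates are 0-based; the text interchange format for
partial columns (and every exported anchor format) is 1-based.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from typing import Iterable, Iterator, NamedTuple, Sequence

from Bio import SeqIO

from .errors import (
    AlphabetError,
    ColumnFormatError,
    DuplicateIdentifierError,
    EmptyInputError,
    FastaError,
    GapCharacterError,
)

__all__ = [
    "Site",
    "SequenceSet",
    "read_fasta",
    "write_fasta",
    "site_space",
    "is_ambiguous",
    "ALPHABETS",
    "GAP_CHARS",
    "read_column_file",
    "write_column_file",
    "format_column_line",
    "parse_column_line",
]

GAP_CHARS = frozenset("-.")

#: Declared alphabets.  Ambiguity codes (X, B, Z for protein; N for DNA)
#: are ordinary symbols matched exactly, never wildcards.
ALPHABETS = {
    "protein": frozenset("ACDEFGHIKLMNPQRSTVWYBJOUXZ*"),
    "dna": frozenset("ACGTUN"),
    "raw": frozenset(c for c in string.printable if not c.isspace()),
}


class Site(NamedTuple):
    """A position in the site space: sequence index and 0-based offset."""

    seq: int
    pos: int


@dataclass(frozen=True)
class SequenceSet:
    """An ordered collection of named, unaligned sequences.

    Parameters
    ----------
    records :
        ``(identifier, residues)`` pairs in input order.  Identifiers must
        be unique and non-empty; residue strings must be non-empty.
    """

    records: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if not self.records:
            raise EmptyInputError("sequence set contains no records")
        seen: set[str] = set()
        for ident, residues in self.records:
            if not ident:
                raise FastaError("empty sequence identifier")
            if ident in seen:
                raise DuplicateIdentifierError(
                    f"duplicate sequence identifier {ident!r}"
                )
            seen.add(ident)
            if not residues:
                raise FastaError(f"sequence {ident!r} has no residues")

    @classmethod
    def from_strings(
        cls, residues: Iterable[str], ids: Iterable[str] | None = None
    ) -> "SequenceSet":
        """Build a set from bare residue strings (ids default to s1, s2, ...)."""
        residues = [r.upper() for r in residues]
        if ids is None:
            ids = [f"s{i + 1}" for i in range(len(residues))]
        return cls(tuple(zip(ids, residues)))

    @property
    def n(self) -> int:
        return len(self.records)

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(ident for ident, _ in self.records)

    @property
    def lengths(self) -> tuple[int, ...]:
        return tuple(len(res) for _, res in self.records)

    def residues(self, seq: int) -> str:
        return self.records[seq][1]

    def residue_at(self, site: Site) -> str:
        return self.records[site.seq][1][site.pos]

    def index_of(self, ident: str) -> int:
        try:
            return self.ids.index(ident)
        except ValueError:
            raise KeyError(f"unknown sequence identifier {ident!r}") from None

    def __len__(self) -> int:
        return self.n

    def __iter__(self) -> Iterator[tuple[str, str]]:
        return iter(self.records)

    @property
    def total_length(self) -> int:
        return sum(self.lengths)


def _validate_residues(ident: str, residues: str, alphabet: str) -> str:
    residues = residues.upper()
    gaps = GAP_CHARS.intersection(residues)
    if gaps:
        raise GapCharacterError(
            f"sequence {ident!r} contains gap character(s) {sorted(gaps)}; "
            "input must be unaligned"
        )
    try:
        allowed = ALPHABETS[alphabet]
    except KeyError:
        raise ValueError(
            f"unknown alphabet {alphabet!r}; choose from {sorted(ALPHABETS)}"
        ) from None
    bad = set(residues) - allowed
    if bad:
        raise AlphabetError(
            f"sequence {ident!r} contains character(s) {sorted(bad)} outside "
            f"the {alphabet} alphabet"
        )
    return residues


def read_fasta(path, alphabet: str = "protein") -> SequenceSet:
    """Read unaligned sequences from a FASTA file.

    Residues are upper-cased before validation.  Gap characters are
    rejected (this stage consumes unaligned sequences only); characters
    outside the declared alphabet raise :class:`AlphabetError` (``raw``
    accepts any printable character).
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append((rec.id, _validate_residues(rec.id, str(rec.seq), alphabet)))
    if not records:
        raise EmptyInputError(f"no FASTA records found in {path}")
    return SequenceSet(tuple(records))


def write_fasta(seqs: SequenceSet, path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for ident, residues in seqs:
            fh.write(f">{ident}\n")
            for i in range(0, len(residues), width):
                fh.write(residues[i : i + width] + "\n")


def site_space(seqs: SequenceSet) -> list[Site]:
    """Enumerate all sites, sequence-major then by position."""
    return [
        Site(i, p) for i in range(seqs.n) for p in range(seqs.lengths[i])
    ]


def is_ambiguous(members: Iterable[Site]) -> bool:
    """True iff some sequence contributes at least two sites.

    An ambiguous site class encodes an internal repeat and can never be
    (part of) an alignment column.  Monotone under set inclusion.
    """
    seen: set[int] = set()
    for site in members:
        if site.seq in seen:
            return True
        seen.add(site.seq)
    return False


# ---------------------------------------------------------------------------
# Partial-column text format: one column per line, whitespace-separated
# `seqid:pos` tokens with 1-based positions.  Used for interchange with the
# consistency engine run standalone, and for fixture truth sets.
# ---------------------------------------------------------------------------


def format_column_line(sites: dict[int, int], seqs: SequenceSet) -> str:
    """Serialize one column (0-based seq->pos mapping) as a text line."""
    return " ".join(
        f"{seqs.ids[s]}:{p + 1}" for s, p in sorted(sites.items())
    )


def parse_column_line(
    line: str, index_of: dict[str, int], lengths: Sequence[int] | None
) -> dict[int, int]:
    sites: dict[int, int] = {}
    for token in line.split():
        ident, _, pos_s = token.rpartition(":")
        if not ident or not pos_s:
            raise ColumnFormatError(f"malformed column token {token!r}")
        try:
            pos = int(pos_s)
        except ValueError:
            raise ColumnFormatError(f"non-integer position in {token!r}") from None
        if pos < 1:
            raise ColumnFormatError(f"positions are 1-based; got {pos} in {token!r}")
        if ident not in index_of:
            raise ColumnFormatError(f"unknown sequence identifier {ident!r}")
        s = index_of[ident]
        if s in sites:
            raise ColumnFormatError(
                f"sequence {ident!r} appears twice in one column line"
            )
        if lengths is not None and pos > lengths[s]:
            raise ColumnFormatError(
                f"position {pos} exceeds length of sequence {ident!r}"
            )
        sites[s] = pos - 1
    if not sites:
        raise ColumnFormatError("empty column line")
    return sites


def read_column_file(path, seqs: SequenceSet | None = None) -> list[dict[int, int]]:
    """Read a partial-column text file.

    With ``seqs`` given, identifiers are resolved against it and positions
    are bounds-checked; otherwise sequence indices are assigned by first
    appearance of each identifier.
    """
    columns: list[dict[int, int]] = []
    if seqs is not None:
        index_of = {ident: i for i, ident in enumerate(seqs.ids)}
        lengths: Sequence[int] | None = seqs.lengths
    else:
        index_of = {}
        lengths = None
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if seqs is None:
                for token in line.split():
                    ident = token.rpartition(":")[0]
                    if ident and ident not in index_of:
                        index_of[ident] = len(index_of)
            columns.append(parse_column_line(line, index_of, lengths))
    return columns


def write_column_file(columns: Iterable[dict[int, int]], seqs: SequenceSet, path) -> None:
    with open(path, "w") as fh:
        for sites in columns:
            fh.write(format_column_line(sites, seqs) + "\n")
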