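"""N-local decoding: clustering sites by shared length-N word contexts.

A word ``w`` of length ``N`` *occurs at position* ``i`` *relative to* a
site ``(s, p)`` when the window ``sequence_s[p - i : p - i + N]`` equals
``w``.  Two sites are directly related when an identical length-``N`` word
occurs at the same relative position for both; a single shared word
occurrence therefore induces ``N`` direct relations, one per offset inside
the word.  The N-local decoding of the site space is the partition induced
by the transitive closure of this relation: two sites land in the same
class when a chain of identical-word occurrences connects them.

The partition is computed by hashing every N-word occurrence and merging,
for each word and each in-word offset, the covered sites of all its
occurrences with a union-find structure — O(total_length * N) per word
length, which is ample at the scale of alignable protein or gene-sized
nucleotide sets.  Words never span sequence boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

from .errors import ParameterError
from .sitespace import SequenceSet, Site, is_ambiguous, site_space

__all__ = ["NldPartition", "nld_partition", "nld_all", "refines"]


class _DSU:
    """Union-find with path halving; representatives resolved at the end."""

    __slots__ = ("parent",)

    def __init__(self, size: int) -> None:
        self.parent = list(range(size))

    def find(self, x: int) -> int:
        parent = self.parent
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            # keep the smaller flat index as root: sequence-major minimum
            if rb < ra:
                ra, rb = rb, ra
            self.parent[rb] = ra


@dataclass(frozen=True)
class NldPartition:
    """The word-context partition of the site space for one word length.

    ``classes`` are pairwise disjoint, cover every site (singletons
    included), and are enumerated in order of their smallest site
    (sequence-major), each class listed with its sites sorted.
    """

    n: int
    classes: tuple[frozenset[Site], ...]
    seqs: SequenceSet = field(repr=False, compare=False)

    def __iter__(self) -> Iterator[frozenset[Site]]:
        return iter(self.classes)

    def __len__(self) -> int:
        return len(self.classes)

    @property
    def all_singletons(self) -> bool:
        return all(len(c) == 1 for c in self.classes)

    def class_of(self) -> dict[Site, int]:
        """Map each site to the index of its class."""
        out: dict[Site, int] = {}
        for k, cls in enumerate(self.classes):
            for site in cls:
                out[site] = k
        return out

    def ambiguous_classes(self) -> tuple[frozenset[Site], ...]:
        return tuple(c for c in self.classes if is_ambiguous(c))


def _flat_offsets(seqs: SequenceSet) -> list[int]:
    offsets = [0]
    for length in seqs.lengths:
        offsets.append(offsets[-1] + length)
    return offsets


def nld_partition(seqs: SequenceSet, n: int) -> NldPartition:
    """Compute the N-local decoding partition for word length ``n``.

    Raises
    ------
    ParameterError
        If ``n`` is smaller than 1 or larger than the longest sequence.
    """
    max_len = max(seqs.lengths)
    if n < 1 or n > max_len:
        raise ParameterError(
            f"word length must satisfy 1 <= N <= {max_len}; got {n}"
        )

    offsets = _flat_offsets(seqs)
    dsu = _DSU(seqs.total_length)

    # first flat site covered by each word's occurrences, word -> flat index
    first_seen: dict[str, int] = {}
    for s in range(seqs.n):
        residues = seqs.residues(s)
        base = offsets[s]
        for q in range(len(residues) - n + 1):
            word = residues[q : q + n]
            start = base + q
            prev = first_seen.setdefault(word, start)
            if prev != start:
                for i in range(n):
                    dsu.union(prev + i, start + i)

    groups: dict[int, list[int]] = {}
    for flat in range(seqs.total_length):
        groups.setdefault(dsu.find(flat), []).append(flat)

    def unflatten(flat: int) -> Site:
        # offsets is sorted; linear scan is fine at desk scale, but bisect
        # keeps it honest for many sequences
        import bisect

        s = bisect.bisect_right(offsets, flat) - 1
        return Site(s, flat - offsets[s])

    classes = tuple(
        frozenset(unflatten(f) for f in members)
        for _, members in sorted(groups.items())
    )
    return NldPartition(n=n, classes=classes, seqs=seqs)


def nld_all(seqs: SequenceSet, n_max: int | None = None) -> list[NldPartition]:
    """Partitions for N = 1, 2, ... until nothing more can split.

    Iteration stops at the first N whose partition is all singletons
    (larger N cannot merge anything new), at the longest sequence length,
    or at ``n_max`` if given — whichever comes first.  The stopping
    partition is included.
    """
    stop = max(seqs.lengths)
    if n_max is not None:
        if n_max < 1:
            raise ParameterError(f"n_max must be >= 1; got {n_max}")
        stop = min(stop, n_max)
    out: list[NldPartition] = []
    for n in range(1, stop + 1):
        part = nld_partition(seqs, n)
        out.append(part)
        if part.all_singletons:
            break
    return out


def refines(finer: NldPartition, coarser: NldPartition) -> bool:
    """True iff every class of ``finer`` lies inside one class of ``coarser``."""
    coarse_of = coarser.class_of()
    for cls in finer.classes:
        ids = {coarse_of[site] for site in cls}
        if len(ids) != 1:
            return False
    return True
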