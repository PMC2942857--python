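"""Partition tree across word lengths and selection of partial columns.

The word-context partitions for successive word lengths refine one
another, so stacking them yields a rooted tree: the root is the whole site
space (word length 0), each node is an equivalence class, and a node's
children are the classes it splits into at the next word length.  Classes
that do not split produce chains of identical nodes — kept distinct on
purpose, which keeps the invariants simple.

A *partial column* is selected at the topmost non-ambiguous frontier: a
node whose class contains at most one site per sequence while its direct
ancestor still contains a repeat.  Such a class is the widest repeat-free
context cluster on its branch; descending further would only shrink it,
and ascending would re-introduce an internal repeat.  Selected columns are
filtered to span at least ``s_min`` distinct sequences (singletons anchor
nothing and are always discarded).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping

from .errors import AmbiguousColumnError, ParameterError
from .nld import NldPartition
from .sitespace import (
    SequenceSet,
    Site,
    format_column_line,
    is_ambiguous,
    read_column_file,
    site_space,
)

__all__ = [
    "PartialColumn",
    "ColumnSet",
    "PartitionTreeNode",
    "PartitionTree",
    "build_partition_tree",
    "select_columns",
    "columns_from_site_maps",
]


@dataclass(frozen=True)
class PartialColumn:
    """A non-ambiguous site set: at most one position per sequence.

    ``sites`` maps sequence index to the (unique) 0-based position the
    column occupies there; ``id`` is a stable ordinal used by the
    succession graph and the anchor writers.
    """

    id: int
    sites: tuple[tuple[int, int], ...]  # sorted (seq, pos) pairs

    @classmethod
    def from_mapping(cls, id: int, sites: Mapping[int, int]) -> "PartialColumn":
        return cls(id=id, sites=tuple(sorted(sites.items())))

    @classmethod
    def from_sites(cls, id: int, members: Iterable[Site]) -> "PartialColumn":
        members = list(members)
        if is_ambiguous(members):
            raise AmbiguousColumnError(
                f"site set {sorted(members)} repeats a sequence"
            )
        return cls.from_mapping(id, {s: p for s, p in members})

    @property
    def mapping(self) -> dict[int, int]:
        return dict(self.sites)

    @property
    def sequences(self) -> tuple[int, ...]:
        return tuple(s for s, _ in self.sites)

    def pos(self, seq: int) -> int:
        """The unique position of this column in sequence ``seq``."""
        for s, p in self.sites:
            if s == seq:
                return p
        raise KeyError(f"column {self.id} does not touch sequence {seq}")

    def touches(self, seq: int) -> bool:
        return any(s == seq for s, _ in self.sites)

    def site_set(self) -> frozenset[Site]:
        return frozenset(Site(s, p) for s, p in self.sites)

    def __len__(self) -> int:
        return len(self.sites)

    def leftmost_key(self) -> tuple[int, int]:
        """Sort key: smallest position, ties broken by sequence index."""
        return min((p, s) for s, p in self.sites)


@dataclass(frozen=True)
class ColumnSet:
    """A collection of pairwise-disjoint partial columns.

    ``s_min`` records the spanning threshold the columns were selected
    with (informational; consistency trimming may later reduce a column
    below it without re-filtering).
    """

    columns: tuple[PartialColumn, ...]
    s_min: int | None = None

    def __iter__(self) -> Iterator[PartialColumn]:
        return iter(self.columns)

    def __len__(self) -> int:
        return len(self.columns)

    def __bool__(self) -> bool:
        return bool(self.columns)

    def by_id(self) -> dict[int, PartialColumn]:
        return {c.id: c for c in self.columns}

    def site_sets(self) -> set[frozenset[Site]]:
        return {c.site_set() for c in self.columns}

    def validate_disjoint(self) -> None:
        seen: set[Site] = set()
        for col in self.columns:
            for site in col.site_set():
                if site in seen:
                    from .errors import OverlappingColumnsError

                    raise OverlappingColumnsError(
                        f"site {site} belongs to two columns"
                    )
                seen.add(site)

    def write(self, seqs: SequenceSet, path) -> None:
        with open(path, "w") as fh:
            for col in self.columns:
                fh.write(format_column_line(col.mapping, seqs) + "\n")

    @classmethod
    def read(cls, path, seqs: SequenceSet | None = None) -> "ColumnSet":
        maps = read_column_file(path, seqs)
        return columns_from_site_maps(maps)


def columns_from_site_maps(
    maps: Iterable[Mapping[int, int]], s_min: int | None = None
) -> ColumnSet:
    """Build a ColumnSet, assigning ids in order of leftmost site."""
    cols = [PartialColumn.from_mapping(0, m) for m in maps]
    cols.sort(key=PartialColumn.leftmost_key)
    cols = [replace(c, id=i) for i, c in enumerate(cols)]
    return ColumnSet(tuple(cols), s_min=s_min)


# ---------------------------------------------------------------------------
# Partition tree
# ---------------------------------------------------------------------------


@dataclass
class PartitionTreeNode:
    level: int
    members: frozenset[Site]
    label: str
    parent: "PartitionTreeNode | None" = None
    children: list["PartitionTreeNode"] = field(default_factory=list)

    @property
    def ambiguous(self) -> bool:
        return is_ambiguous(self.members)

    @property
    def n_sequences(self) -> int:
        return len({s.seq for s in self.members})

    def __repr__(self) -> str:  # keep dataclass repr from recursing
        return f"PartitionTreeNode({self.label}, level={self.level}, size={len(self.members)})"


@dataclass
class PartitionTree:
    """Rooted tree of word-context classes across word lengths.

    Level 0 is the root (the full site space); level ``N`` holds the
    classes of the length-``N`` decoding.  Leaves are single sites: when
    the deepest decoding still contains multi-site classes (iteration
    capped, or stopped at the maximum sequence length), an extra level of
    singleton leaves is appended so that every site terminates a
    root-to-leaf chain.
    """

    root: PartitionTreeNode
    levels: list[list[PartitionTreeNode]]
    seqs: SequenceSet

    def nodes(self) -> Iterator[PartitionTreeNode]:
        for level in self.levels:
            yield from level

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    def to_dot(self) -> str:
        """GraphViz rendering for inspection; ambiguous nodes in red."""
        lines = ["digraph partition_tree {", "  node [shape=box];"]
        ids = {id(n): f"n{i}" for i, n in enumerate(self.nodes())}
        for node in self.nodes():
            colour = "red" if node.ambiguous else "darkgreen"
            lines.append(
                f'  {ids[id(node)]} [label="{node.label}\\n{len(node.members)} sites", color={colour}];'
            )
            for child in node.children:
                lines.append(f"  {ids[id(node)]} -> {ids[id(child)]};")
        lines.append("}")
        return "\n".join(lines)


def build_partition_tree(partitions: list[NldPartition]) -> PartitionTree:
    """Stack successive word-length partitions into a tree.

    ``partitions`` must be the decodings for N = 1 .. N_stop of a single
    sequence set, in order (as produced by :func:`ms4anchors.nld.nld_all`).
    Mutual refinement is an invariant of the decoding; it is asserted here
    as an internal check, not a recoverable error.
    """
    if not partitions:
        raise ParameterError("need at least one partition to build a tree")
    seqs = partitions[0].seqs
    all_sites = frozenset(site_space(seqs))
    root = PartitionTreeNode(level=0, members=all_sites, label="E0")
    levels: list[list[PartitionTreeNode]] = [[root]]

    parent_of: dict[Site, PartitionTreeNode] = {site: root for site in all_sites}
    for part in partitions:
        level_nodes: list[PartitionTreeNode] = []
        next_parent: dict[Site, PartitionTreeNode] = {}
        for ordinal, cls in enumerate(part.classes):
            rep = min(cls)
            parent = parent_of[rep]
            assert cls <= parent.members, "decodings are not mutually refining"
            label = f"{seqs.residue_at(rep)}{ordinal}_{part.n}"
            node = PartitionTreeNode(
                level=part.n, members=cls, label=label, parent=parent
            )
            parent.children.append(node)
            level_nodes.append(node)
            for site in cls:
                next_parent[site] = node
        parent_of = next_parent
        levels.append(level_nodes)

    # ensure leaves are single sites
    deepest = levels[-1]
    if any(len(node.members) > 1 for node in deepest):
        leaf_level: list[PartitionTreeNode] = []
        depth = deepest[0].level + 1
        for node in deepest:
            for ordinal, site in enumerate(sorted(node.members)):
                leaf = PartitionTreeNode(
                    level=depth,
                    members=frozenset([site]),
                    label=f"{seqs.residue_at(site)}{site.seq}.{site.pos}_leaf",
                    parent=node,
                )
                node.children.append(leaf)
                leaf_level.append(leaf)
        levels.append(leaf_level)

    return PartitionTree(root=root, levels=levels, seqs=seqs)


def select_columns(tree: PartitionTree, s_min: int) -> ColumnSet:
    """Select partial columns at the topmost non-ambiguous frontier.

    A node is selected when it is non-ambiguous, its direct ancestor is
    ambiguous, it contains at least two sites, and it touches at least
    ``s_min`` distinct sequences.  Chains of identical classes contribute
    only their shallowest node (the deeper copies have a non-ambiguous
    parent and fail the frontier test), so selected columns are pairwise
    disjoint by construction.
    """
    if s_min < 2:
        raise ParameterError(f"s_min must be >= 2; got {s_min}")
    picked: list[frozenset[Site]] = []
    for node in tree.nodes():
        if node.parent is None or node.ambiguous or not node.parent.ambiguous:
            continue
        if len(node.members) < 2:
            continue
        if node.n_sequences < s_min:
            continue
        picked.append(node.members)
    maps = [{site.seq: site.pos for site in members} for members in picked]
    cs = columns_from_site_maps(maps, s_min=s_min)
    cs.validate_disjoint()
    return cs
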