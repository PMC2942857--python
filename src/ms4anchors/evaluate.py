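"""Alignment scoring: sum-of-pairs, total-column, and specificity.

A multiple alignment is viewed as a partition of the site space: each
alignment column groups the ungapped residue positions it contains.  The
scores compare a *test* alignment with a *reference* over a set of
reference *core* columns:

* **SP** (sum-of-pairs): percentage of residue pairs aligned together in
  the reference core columns that the test alignment also aligns.
* **TC** (total-column): percentage of reference core columns whose whole
  residue set is aligned as one column in the test alignment — a single
  misplaced residue zeroes the column's contribution.
* **Specificity**: the argument-swapped measures — among the pairs
  (columns) that the *test* aligns over core residues, the proportion
  that are correct per the reference.  SP/TC measure sensitivity, these
  measure precision.

Core columns are given as a plain mask of 1-based reference column
indices (or ``"all"``); the module is deliberately benchmark-agnostic.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable

from Bio import SeqIO

from .errors import FastaError, SequenceMismatchError, UndefinedScoreError
from .sitespace import GAP_CHARS, Site

__all__ = [
    "Alignment",
    "read_alignment",
    "CoreMask",
    "sp_score",
    "tc_score",
    "specificity",
]


@dataclass(frozen=True)
class Alignment:
    """Rows of equal gapped length; ungapping reproduces the sequences."""

    rows: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if not self.rows:
            raise FastaError("alignment has no rows")
        widths = {len(text) for _, text in self.rows}
        if len(widths) != 1:
            raise FastaError("alignment rows have unequal lengths")
        ids = [ident for ident, _ in self.rows]
        if len(set(ids)) != len(ids):
            raise FastaError("duplicate row identifiers in alignment")

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_cols(self) -> int:
        return len(self.rows[0][1])

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(ident for ident, _ in self.rows)

    def ungapped(self, row: int) -> str:
        return "".join(c for c in self.rows[row][1] if c not in GAP_CHARS)

    def site_grid(self) -> list[list[int | None]]:
        """Per row, per column: the ungapped position, or None at a gap."""
        grid: list[list[int | None]] = []
        for _, text in self.rows:
            pos = 0
            row: list[int | None] = []
            for c in text:
                if c in GAP_CHARS:
                    row.append(None)
                else:
                    row.append(pos)
                    pos += 1
            grid.append(row)
        return grid

    def column_sites(self, row_order: Iterable[int] | None = None) -> list[frozenset[Site]]:
        """Per column, the set of (row, ungapped position) sites.

        ``row_order`` optionally remaps row indices (used to express test
        rows in reference row numbering).
        """
        grid = self.site_grid()
        mapping = list(row_order) if row_order is not None else list(range(self.n_rows))
        out: list[frozenset[Site]] = []
        for j in range(self.n_cols):
            sites = frozenset(
                Site(mapping[i], grid[i][j])
                for i in range(self.n_rows)
                if grid[i][j] is not None
            )
            out.append(sites)
        return out


def read_alignment(path) -> Alignment:
    rows = [
        (rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not rows:
        raise FastaError(f"no alignment records found in {path}")
    return Alignment(tuple(rows))


@dataclass(frozen=True)
class CoreMask:
    """Reference core columns: ``"all"`` or 1-based column indices."""

    spec: tuple[int, ...] | str = "all"

    @classmethod
    def from_indices(cls, indices: Iterable[int]) -> "CoreMask":
        return cls(tuple(sorted(set(indices))))

    @classmethod
    def parse(cls, text: str) -> "CoreMask":
        """Parse ``"all"`` or a 1-based list like ``"1,3,5-9"``."""
        text = text.strip().lower()
        if text == "all":
            return cls("all")
        indices: set[int] = set()
        for part in text.split(","):
            part = part.strip()
            if "-" in part:
                lo, hi = part.split("-", 1)
                indices.update(range(int(lo), int(hi) + 1))
            elif part:
                indices.add(int(part))
        return cls.from_indices(indices)

    def columns(self, n_cols: int) -> list[int]:
        """Resolve to 0-based column indices within an alignment width."""
        if self.spec == "all":
            return list(range(n_cols))
        for idx in self.spec:
            if not 1 <= idx <= n_cols:
                raise UndefinedScoreError(
                    f"core column {idx} outside alignment width {n_cols}"
                )
        return [i - 1 for i in self.spec]


def _match_rows(test: Alignment, ref: Alignment) -> list[int]:
    """For each test row, the index of the reference row it realises."""
    ref_index = {ident: i for i, (ident, _) in enumerate(ref.rows)}
    if set(test.ids) != set(ref_index):
        raise SequenceMismatchError(
            "test and reference alignments name different sequences"
        )
    order: list[int] = []
    for i, (ident, _) in enumerate(test.rows):
        j = ref_index[ident]
        if test.ungapped(i) != ref.ungapped(j):
            raise SequenceMismatchError(
                f"sequence {ident!r} differs between test and reference"
            )
        order.append(j)
    return order


def _aligned_pairs(columns: Iterable[frozenset[Site]]) -> set[tuple[Site, Site]]:
    pairs: set[tuple[Site, Site]] = set()
    for sites in columns:
        for a, b in combinations(sorted(sites), 2):
            pairs.add((a, b))
    return pairs


def _core_sites(ref: Alignment, core: CoreMask) -> frozenset[Site]:
    cols = ref.column_sites()
    chosen = core.columns(ref.n_cols)
    return frozenset().union(*[cols[j] for j in chosen]) if chosen else frozenset()


def sp_score(
    test: Alignment,
    ref: Alignment,
    core: CoreMask = CoreMask("all"),
    *,
    core_sites: frozenset[Site] | None = None,
) -> float:
    """Percentage of reference core residue pairs reproduced by the test.

    ``core_sites`` overrides the column mask with an explicit residue
    set (expressed in reference row numbering); pairs then count when
    both endpoints are core, whichever reference column holds them.  For
    a column-derived mask the two readings coincide, since a pair within
    a column consists of that column's sites only.
    """
    order = _match_rows(test, ref)
    if core_sites is None:
        core_sites = _core_sites(ref, core)
    ref_pairs = {
        (a, b)
        for a, b in _aligned_pairs(ref.column_sites())
        if a in core_sites and b in core_sites
    }
    if not ref_pairs:
        raise UndefinedScoreError("reference has no core residue pairs")
    test_pairs = _aligned_pairs(test.column_sites(row_order=order))
    return 100.0 * len(ref_pairs & test_pairs) / len(ref_pairs)


def tc_score(
    test: Alignment,
    ref: Alignment,
    core: CoreMask = CoreMask("all"),
    *,
    core_sites: frozenset[Site] | None = None,
) -> float:
    """Percentage of reference core columns aligned intact in the test.

    With a column mask, every masked column counts in the denominator
    regardless of gap content; a column with at most one residue is
    vacuously intact.  With an explicit ``core_sites`` set, reference
    columns are restricted to core residues and only those with a
    non-empty restriction count.
    """
    order = _match_rows(test, ref)
    ref_columns = ref.column_sites()
    if core_sites is None:
        chosen = [ref_columns[j] for j in core.columns(ref.n_cols)]
    else:
        chosen = [
            c & core_sites for c in ref_columns if c & core_sites
        ]
    if not chosen:
        raise UndefinedScoreError("no core columns in the reference")
    test_of_site: dict[Site, int] = {}
    for j, sites in enumerate(test.column_sites(row_order=order)):
        for site in sites:
            test_of_site[site] = j
    test_columns = test.column_sites(row_order=order)
    intact = 0
    for sites in chosen:
        if len(sites) <= 1:
            intact += 1
            continue
        probe = next(iter(sites))
        if sites <= test_columns[test_of_site[probe]]:
            intact += 1
    return 100.0 * intact / len(chosen)


def specificity(
    test: Alignment, ref: Alignment, core: CoreMask = CoreMask("all")
) -> tuple[float, float]:
    """Argument-swapped (precision-like) SP and TC.

    ``sp_spec``: among test-aligned residue pairs whose endpoints both
    lie in reference core columns, the percentage also aligned in the
    reference.  ``tc_spec``: among test columns with core residues, the
    percentage whose core restriction sits intact inside one reference
    column.  Computed directly here; equals the ordinary scorers with
    test and reference swapped and the core transported as a residue set.
    """
    order = _match_rows(test, ref)
    core_sites = _core_sites(ref, core)
    test_columns = test.column_sites(row_order=order)
    ref_columns = ref.column_sites()

    test_core_pairs = {
        (a, b)
        for a, b in _aligned_pairs(test_columns)
        if a in core_sites and b in core_sites
    }
    if not test_core_pairs:
        raise UndefinedScoreError("test aligns no core residue pairs")
    ref_pairs = _aligned_pairs(ref_columns)
    sp_spec = 100.0 * len(test_core_pairs & ref_pairs) / len(test_core_pairs)

    ref_of_site: dict[Site, int] = {}
    for j, sites in enumerate(ref_columns):
        for site in sites:
            ref_of_site[site] = j
    restricted = [c & core_sites for c in test_columns if c & core_sites]
    if not restricted:
        raise UndefinedScoreError("test has no columns over core residues")
    intact = 0
    for sites in restricted:
        if len(sites) <= 1:
            intact += 1
            continue
        probe = next(iter(sites))
        if sites <= ref_columns[ref_of_site[probe]]:
            intact += 1
    tc_spec = 100.0 * intact / len(restricted)
    return sp_spec, tc_spec
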