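"""Independent brute-force oracles and random-instance generators.

Everything here deliberately avoids the code paths it checks: the word
clustering oracle materialises the direct relation and takes connected
components with networkx; the consistency oracle works at the site level
(order-theoretic definition) instead of the column-level succession
graph; the scorers enumerate pairs and columns by nested scanning.
"""

from __future__ import annotations

import random
from itertools import combinations

import networkx as nx

from ms4anchors.ms4 import ColumnSet, columns_from_site_maps
from ms4anchors.sitespace import SequenceSet, Site, site_space

# ---------------------------------------------------------------------------
# Word-context clustering oracle
# ---------------------------------------------------------------------------


def nld_oracle(seqs: SequenceSet, n: int) -> set[frozenset[Site]]:
    """Partition by explicit relation construction + transitive closure.

    Enumerate every occurrence of every length-``n`` word; for each word,
    link the covered sites of its occurrences offset by offset; take
    connected components of the resulting undirected relation graph.
    """
    g = nx.Graph()
    g.add_nodes_from(site_space(seqs))
    occurrences: dict[str, list[tuple[int, int]]] = {}
    for s in range(seqs.n):
        residues = seqs.residues(s)
        for q in range(len(residues) - n + 1):
            occurrences.setdefault(residues[q : q + n], []).append((s, q))
    for occs in occurrences.values():
        for (s1, q1), (s2, q2) in zip(occs, occs[1:]):
            for i in range(n):
                g.add_edge(Site(s1, q1 + i), Site(s2, q2 + i))
    return {frozenset(comp) for comp in nx.connected_components(g)}


def random_sequence_set(rng: random.Random, alphabet_size: int | None = None) -> SequenceSet:
    alphabets = {2: "AB", 4: "ACGT", 20: "ACDEFGHIKLMNPQRSTVWY"}
    if alphabet_size is None:
        alphabet_size = rng.choice([2, 4, 20])
    alphabet = alphabets[alphabet_size]
    n_seqs = rng.randint(2, 8)
    seqs = []
    for _ in range(n_seqs):
        length = rng.randint(3, 40)
        seqs.append("".join(rng.choice(alphabet) for _ in range(length)))
    return SequenceSet.from_strings(seqs)


# ---------------------------------------------------------------------------
# Order-theoretic consistency oracle (site level)
# ---------------------------------------------------------------------------


def consistency_oracle(cols: ColumnSet, lengths: list[int]) -> bool:
    """Consistency per the order-closure definition.

    Build the preorder generated by (a) each sequence's left-to-right
    successor relation and (b) the symmetric co-column relation; the set
    is consistent iff the closure, restricted to any sequence, never
    orders a later position before an earlier one — equivalently, no
    strongly connected component contains two sites of one sequence.
    """
    g = nx.DiGraph()
    for s, length in enumerate(lengths):
        for p in range(length):
            g.add_node(Site(s, p))
            if p:
                g.add_edge(Site(s, p - 1), Site(s, p))
    for col in cols:
        sites = [Site(s, p) for s, p in col.sites]
        for a, b in combinations(sites, 2):
            g.add_edge(a, b)
            g.add_edge(b, a)
    for comp in nx.strongly_connected_components(g):
        seen: set[int] = set()
        for site in comp:
            if site.seq in seen:
                return False
            seen.add(site.seq)
    return True


def random_column_set(
    rng: random.Random,
    n_seqs: int | None = None,
    length: int | None = None,
    max_cols: int = 6,
) -> tuple[ColumnSet, list[int]]:
    """Random disjoint non-ambiguous columns over a rectangular site grid."""
    if n_seqs is None:
        n_seqs = rng.randint(2, 4)
    if length is None:
        length = rng.randint(3, 6)
    free = {s: list(range(length)) for s in range(n_seqs)}
    maps = []
    for _ in range(rng.randint(1, max_cols)):
        eligible = [s for s in free if len(free[s]) > 0]
        if len(eligible) < 2:
            break
        k = rng.randint(2, len(eligible))
        chosen = rng.sample(eligible, k)
        col = {}
        for s in chosen:
            p = rng.choice(free[s])
            free[s].remove(p)
            col[s] = p
        maps.append(col)
    return columns_from_site_maps(maps), [length] * n_seqs


def cyclic_column_set(rng: random.Random) -> tuple[ColumnSet, list[int]]:
    """Adversarial instance: per-sequence column orders drawn as random
    permutations, which manufactures succession cycles with high
    probability."""
    n_seqs = rng.randint(3, 5)
    n_cols = rng.randint(3, 6)
    length = n_cols
    maps: list[dict[int, int]] = [dict() for _ in range(n_cols)]
    for s in range(n_seqs):
        order = list(range(n_cols))
        rng.shuffle(order)
        for p, cid in enumerate(order):
            if rng.random() < 0.85:
                maps[cid][s] = p
    maps = [m for m in maps if len(m) >= 2]
    return columns_from_site_maps(maps), [length] * n_seqs


# ---------------------------------------------------------------------------
# Alignment scoring oracles
# ---------------------------------------------------------------------------


def sp_oracle(test, ref, core_columns: list[int]) -> float:
    """Sum-of-pairs by nested scanning of rows and columns."""
    ref_grid = ref.site_grid()
    order = {ident: i for i, (ident, _) in enumerate(ref.rows)}
    test_grid = test.site_grid()
    test_row_of_ref = {order[ident]: i for i, (ident, _) in enumerate(test.rows)}

    def aligned_in_test(i1, p1, i2, p2) -> bool:
        r1, r2 = test_row_of_ref[i1], test_row_of_ref[i2]
        for j in range(test.n_cols):
            if test_grid[r1][j] == p1 and test_grid[r2][j] == p2:
                return True
        return False

    total = hits = 0
    for j in core_columns:
        present = [
            (i, ref_grid[i][j]) for i in range(ref.n_rows) if ref_grid[i][j] is not None
        ]
        for (i1, p1), (i2, p2) in combinations(present, 2):
            total += 1
            if aligned_in_test(i1, p1, i2, p2):
                hits += 1
    if total == 0:
        raise ZeroDivisionError("no core pairs")
    return 100.0 * hits / total


def tc_oracle(test, ref, core_columns: list[int]) -> float:
    """Total-column score by direct column matching."""
    ref_grid = ref.site_grid()
    order = {ident: i for i, (ident, _) in enumerate(ref.rows)}
    test_grid = test.site_grid()
    test_row_of_ref = {order[ident]: i for i, (ident, _) in enumerate(test.rows)}

    intact = 0
    for j in core_columns:
        present = [
            (i, ref_grid[i][j]) for i in range(ref.n_rows) if ref_grid[i][j] is not None
        ]
        if len(present) <= 1:
            intact += 1
            continue
        ok = False
        for jt in range(test.n_cols):
            if all(
                test_grid[test_row_of_ref[i]][jt] == p for i, p in present
            ):
                ok = True
                break
        if ok:
            intact += 1
    return 100.0 * intact / len(core_columns)


def random_alignment_pair(rng: random.Random):
    """Two random alignments of the same random sequences."""
    from ms4anchors.evaluate import Alignment

    n_rows = rng.randint(2, 4)
    seqs = []
    for _ in range(n_rows):
        length = rng.randint(3, 8)
        seqs.append("".join(rng.choice("ACDEFG") for _ in range(length)))

    def randomly_align(strings):
        width = max(len(s) for s in strings) + rng.randint(0, 4)
        rows = []
        for s in strings:
            gap_at = set(rng.sample(range(width), width - len(s)))
            it = iter(s)
            rows.append(
                "".join("-" if j in gap_at else next(it) for j in range(width))
            )
        return rows

    ids = [f"r{i}" for i in range(n_rows)]
    test = Alignment(tuple(zip(ids, randomly_align(seqs))))
    ref = Alignment(tuple(zip(ids, randomly_align(seqs))))
    return test, ref
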