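"""Order-consistency filtering of partial columns.

A set of partial columns can be added to a multiple alignment only when
the precedence it induces never contradicts the left-to-right order of any
sequence.  This condition is captured by the *succession graph*: a
weighted digraph on the columns with an edge ``u -> v`` whenever some
sequence contains ``u`` strictly left of ``v``, weighted by the number of
such sequences.  The column set is consistent exactly when this graph is
acyclic.

Inconsistencies are removed in two steps:

1. *dagify* — a heuristic for the (NP-hard) minimum weighted feedback arc
   set problem: drop all inter-column edges of weight <= k for the
   smallest threshold ``k*`` that leaves an acyclic graph, then reconnect
   isolated columns to the start/end markers.  Edges incident to the
   markers are never dropped.  If the input graph is already acyclic the
   threshold is 0 and nothing is removed (filtering an acyclic graph
   would only weaken the induced order and cost sites for no benefit).

2. *resolve* — per sequence, intersect the DAG order (via its transitive
   closure) with the sequence's own left-to-right order of columns; the
   chains of this intersection are exactly the occurrence subsets that
   are mutually consistent.  A maximum-length start-to-end chain is kept
   and every column off the chain loses its site in that sequence.
   Sequences are independent — each reads only the closed DAG and its own
   site order — so processing order cannot change the outcome.

The succession graph of the trimmed column set is guaranteed acyclic;
this is asserted after every resolution.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Hashable, Iterable, Sequence

import networkx as nx

from .errors import AmbiguousColumnError
from .ms4 import ColumnSet, PartialColumn

__all__ = [
    "V_START",
    "V_END",
    "build_succession_graph",
    "is_consistent",
    "dagify",
    "DagifyResult",
    "resolve",
    "ResolutionTrace",
    "consistent_columns",
]

#: Distinguished start/end markers of the succession graph.
V_START: str = "__start__"
V_END: str = "__end__"

Edge = tuple[Hashable, Hashable]


def _check_contract(cols: ColumnSet) -> None:
    for col in cols:
        seqs = [s for s, _ in col.sites]
        if len(seqs) != len(set(seqs)):
            raise AmbiguousColumnError(f"column {col.id} repeats a sequence")
    cols.validate_disjoint()


def _columns_by_sequence(cols: ColumnSet) -> dict[int, list[PartialColumn]]:
    """Columns touching each sequence, sorted left to right."""
    per_seq: dict[int, list[PartialColumn]] = {}
    for col in cols:
        for s, _ in col.sites:
            per_seq.setdefault(s, []).append(col)
    for s, lst in per_seq.items():
        lst.sort(key=lambda c: c.pos(s))
    return per_seq


def build_succession_graph(cols: ColumnSet) -> nx.DiGraph:
    """Weighted digraph of left-to-right precedence between columns.

    Nodes are column ids plus :data:`V_START` / :data:`V_END`.  An edge
    ``u -> v`` carries weight = number of sequences in which ``u`` lies
    strictly left of ``v`` (over all pairs, not just adjacent ones).
    ``V_START`` points to every column that is leftmost in at least one
    sequence; dually for ``V_END``.
    """
    _check_contract(cols)
    g = nx.DiGraph()
    g.add_node(V_START)
    g.add_node(V_END)
    g.add_nodes_from(col.id for col in cols)
    per_seq = _columns_by_sequence(cols)
    for s, ordered in per_seq.items():
        for i, u in enumerate(ordered):
            for v in ordered[i + 1 :]:
                if g.has_edge(u.id, v.id):
                    g[u.id][v.id]["weight"] += 1
                else:
                    g.add_edge(u.id, v.id, weight=1)
        first, last = ordered[0], ordered[-1]
        for a, b in ((V_START, first.id), (last.id, V_END)):
            if g.has_edge(a, b):
                g[a][b]["weight"] += 1
            else:
                g.add_edge(a, b, weight=1)
    return g


def _inter_column_edges(g: nx.DiGraph) -> list[Edge]:
    return [
        (u, v) for u, v in g.edges if u not in (V_START, V_END) and v not in (V_START, V_END)
    ]


def is_consistent(cols: ColumnSet) -> bool:
    """True iff the columns admit a multiple alignment (acyclic succession)."""
    if not cols:
        return True
    g = build_succession_graph(cols)
    return nx.is_directed_acyclic_graph(g)


@dataclass(frozen=True)
class DagifyResult:
    """Outcome of the weight-threshold feedback-arc-set heuristic."""

    graph: nx.DiGraph  # the reconnected DAG G*
    k_star: int
    kept_edges: frozenset[Edge]
    removed_edges: frozenset[Edge]


def dagify(g: nx.DiGraph) -> DagifyResult:
    """Remove lowest-weight inter-column edges until the graph is acyclic.

    ``k*`` is the smallest integer threshold such that keeping only the
    inter-column edges of weight > k (marker edges are always kept)
    yields a DAG.  ``k* = 0`` means the graph was already acyclic.  After
    filtering, any column left without a predecessor (resp. successor) is
    reconnected to the start (resp. end) marker so every column lies on a
    start-to-end path.
    """
    inter = _inter_column_edges(g)
    max_w = max((g[u][v]["weight"] for u, v in inter), default=0)
    k_star = 0
    dag: nx.DiGraph | None = None
    for k in range(0, max_w + 1):
        cand = nx.DiGraph()
        cand.add_nodes_from(g.nodes)
        for u, v in g.edges:
            if u in (V_START, V_END) or v in (V_START, V_END) or g[u][v]["weight"] > k:
                cand.add_edge(u, v, weight=g[u][v]["weight"])
        if nx.is_directed_acyclic_graph(cand):
            k_star = k
            dag = cand
            break
    assert dag is not None  # k = max_w leaves no inter-column edge
    kept = frozenset(dag.edges)
    removed = frozenset(e for e in inter if e not in kept)
    for node in list(dag.nodes):
        if node in (V_START, V_END):
            continue
        if dag.in_degree(node) == 0:
            dag.add_edge(V_START, node, weight=0)
        if dag.out_degree(node) == 0:
            dag.add_edge(node, V_END, weight=0)
    return DagifyResult(
        graph=dag, k_star=k_star, kept_edges=kept, removed_edges=removed
    )


@dataclass(frozen=True)
class ResolutionTrace:
    """Full provenance of one consistency resolution.

    ``chains`` maps each sequence to the column-id chain it kept (the
    maximum-length path through the intersected order); ``removed`` lists
    ``(sequence, column_id)`` for every site trimmed; ``columns`` is the
    final consistent column set (columns reduced below two sites are
    dropped).
    """

    chains: dict[int, tuple[int, ...]]
    removed: frozenset[tuple[int, int]]
    columns: ColumnSet
    k_star: int
    dag: DagifyResult
    dropped_columns: frozenset[int] = frozenset()

    @property
    def n_removed_sites(self) -> int:
        return len(self.removed)


def _better(a, b) -> bool:
    """Chain preference: longer, then larger total column size, then
    lexicographically smaller id sequence."""
    if a[0] != b[0]:
        return a[0] > b[0]
    if a[1] != b[1]:
        return a[1] > b[1]
    return a[2] < b[2]


def _longest_chain(
    ordered: Sequence[int],
    e_plus: set[Edge],
    sizes: dict[int, int],
) -> tuple[int, ...]:
    """Maximum-length start-to-end chain over columns ``ordered`` by position.

    The graph of the intersected relation is a DAG whose topological
    order is the sequence's own left-to-right order, so a single DP pass
    suffices.  State per node: (number of columns, total column size,
    id tuple); ties resolved by :func:`_better`.  Prefix optimality holds
    for all three components, so the greedy per-node choice is exact.
    """
    order: list[Hashable] = [V_START, *ordered, V_END]
    best: dict[Hashable, tuple[int, int, tuple[int, ...]]] = {
        V_START: (0, 0, ())
    }
    for idx in range(1, len(order)):
        v = order[idx]
        cand = None
        for u in order[:idx]:
            if u not in best or (u, v) not in e_plus:
                continue
            length, size, path = best[u]
            if v is not V_END:
                entry = (length + 1, size + sizes[v], path + (v,))
            else:
                entry = (length, size, path)
            if cand is None or _better(entry, cand):
                cand = entry
        if cand is not None:
            best[v] = cand
    assert V_END in best, "no start-to-end chain; reconnection failed"
    return best[V_END][2]


def resolve(cols: ColumnSet, _sequence_order: Iterable[int] | None = None) -> ResolutionTrace:
    """Trim sites so that the remaining columns are consistent.

    Builds the succession graph, dagifies it, closes the DAG
    transitively, and then, for every sequence independently, keeps a
    maximum-length chain of column occurrences compatible with both the
    DAG order and the sequence order; sites of off-chain columns are
    removed.  ``_sequence_order`` only changes the iteration order (for
    testing order-independence); results are identical for any order.
    """
    _check_contract(cols)
    if not cols:
        empty = DagifyResult(nx.DiGraph(), 0, frozenset(), frozenset())
        return ResolutionTrace(
            chains={},
            removed=frozenset(),
            columns=ColumnSet((), s_min=cols.s_min),
            k_star=0,
            dag=empty,
        )
    g = build_succession_graph(cols)
    dag_result = dagify(g)
    closure = nx.transitive_closure_dag(dag_result.graph)
    e_plus: set[Edge] = set(closure.edges)
    # the empty chain must remain available even in a single-column graph
    e_plus.add((V_START, V_END))

    sizes = {col.id: len(col) for col in cols}
    per_seq = _columns_by_sequence(cols)
    seq_ids = list(per_seq) if _sequence_order is None else [
        s for s in _sequence_order if s in per_seq
    ]
    if _sequence_order is not None and set(seq_ids) != set(per_seq):
        missing = set(per_seq) - set(seq_ids)
        raise ValueError(f"sequence order omits sequences {sorted(missing)}")

    chains: dict[int, tuple[int, ...]] = {}
    removed: set[tuple[int, int]] = set()
    for s in seq_ids:
        ordered = [col.id for col in per_seq[s]]
        chain = _longest_chain(ordered, e_plus, sizes)
        chains[s] = chain
        kept = set(chain)
        for cid in ordered:
            if cid not in kept:
                removed.add((s, cid))

    final: list[PartialColumn] = []
    dropped: set[int] = set()
    for col in cols:
        surviving = tuple(
            (s, p) for s, p in col.sites if (s, col.id) not in removed
        )
        if len(surviving) >= 2:
            final.append(replace(col, sites=surviving))
        else:
            dropped.add(col.id)
    out = ColumnSet(tuple(final), s_min=cols.s_min)

    assert is_consistent(out), "resolution produced an inconsistent column set"
    return ResolutionTrace(
        chains=chains,
        removed=frozenset(removed),
        columns=out,
        k_star=dag_result.k_star,
        dag=dag_result,
        dropped_columns=frozenset(dropped),
    )


def consistent_columns(cols: ColumnSet) -> ColumnSet:
    """The consistent column set produced by :func:`resolve`."""
    return resolve(cols).columns
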