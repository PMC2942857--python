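"""Succession graph, feedback-arc heuristic, and site-removal algorithm."""

import random
from itertools import permutations

import networkx as nx
import pytest

from ms4anchors.consistency import (
    V_END,
    V_START,
    build_succession_graph,
    consistent_columns,
    dagify,
    is_consistent,
    resolve,
)
from ms4anchors.errors import AmbiguousColumnError, OverlappingColumnsError
from ms4anchors.ms4 import ColumnSet, PartialColumn, columns_from_site_maps
from oracles import consistency_oracle, cyclic_column_set, random_column_set


def cols_of(*maps):
    return columns_from_site_maps(list(maps))


class TestSuccessionGraph:
    def test_crossing_pair_forms_two_cycle(self):
        cols = cols_of({0: 0, 1: 1}, {0: 1, 1: 0})
        g = build_succession_graph(cols)
        a, b = cols.columns[0].id, cols.columns[1].id
        assert g[a][b]["weight"] == 1
        assert g[b][a]["weight"] == 1

    def test_parallel_pair_single_weighted_edge(self):
        cols = cols_of({0: 0, 1: 0}, {0: 1, 1: 1})
        g = build_succession_graph(cols)
        assert g[0][1]["weight"] == 2
        assert not g.has_edge(1, 0)

    def test_single_column_wires_markers_only(self):
        cols = cols_of({0: 0, 1: 0})
        g = build_succession_graph(cols)
        assert set(g.edges) == {(V_START, 0), (0, V_END)}

    def test_marker_degrees(self):
        cols = cols_of({0: 0, 1: 1}, {0: 1, 1: 0}, {0: 2, 1: 2})
        g = build_succession_graph(cols)
        assert g.in_degree(V_START) == 0
        assert g.out_degree(V_END) == 0

    def test_ambiguous_input_rejected(self):
        bad = ColumnSet((PartialColumn(0, ((0, 0), (0, 2), (1, 0))),))
        with pytest.raises(AmbiguousColumnError):
            build_succession_graph(bad)

    def test_overlapping_input_rejected(self):
        bad = ColumnSet(
            (PartialColumn(0, ((0, 0), (1, 0))), PartialColumn(1, ((0, 0), (1, 1))))
        )
        with pytest.raises(OverlappingColumnsError):
            build_succession_graph(bad)


class TestIsConsistent:
    def test_parallel_columns_consistent(self):
        assert is_consistent(cols_of({0: 0, 1: 0}, {0: 1, 1: 1}))

    def test_crossing_columns_inconsistent(self):
        assert not is_consistent(cols_of({0: 0, 1: 1}, {0: 1, 1: 0}))

    @pytest.mark.parametrize("seed", range(40))
    def test_agrees_with_order_closure_oracle(self, seed):
        rng = random.Random(seed)
        maker = cyclic_column_set if seed % 2 else random_column_set
        cols, lengths = maker(rng)
        assert is_consistent(cols) == consistency_oracle(cols, lengths)


class TestDagify:
    def test_majority_edge_survives(self):
        cols = cols_of({0: 0, 1: 0, 2: 1}, {0: 1, 1: 1, 2: 0})
        g = build_succession_graph(cols)  # A->B weight 2, B->A weight 1
        res = dagify(g)
        assert res.k_star == 1
        assert res.removed_edges == {(1, 0)}

    def test_acyclic_graph_untouched(self):
        cols = cols_of({0: 0, 1: 0}, {0: 1, 1: 1})
        res = dagify(build_succession_graph(cols))
        assert res.k_star == 0
        assert not res.removed_edges

    def test_balanced_two_cycle_loses_both_edges_and_reconnects(self):
        cols = cols_of({0: 0, 1: 1}, {0: 1, 1: 0})
        res = dagify(build_succession_graph(cols))
        assert res.k_star == 1
        assert res.removed_edges == {(0, 1), (1, 0)}
        for cid in (0, 1):
            assert res.graph.has_edge(V_START, cid)
            assert res.graph.has_edge(cid, V_END)

    @staticmethod
    def random_weighted_digraph(rng):
        g = nx.DiGraph()
        n = rng.randint(2, 7)
        g.add_nodes_from([V_START, V_END, *range(n)])
        for u in range(n):
            for v in range(n):
                if u != v and rng.random() < 0.4:
                    g.add_edge(u, v, weight=rng.randint(1, 5))
        for u in range(n):
            if rng.random() < 0.5:
                g.add_edge(V_START, u, weight=1)
            if rng.random() < 0.5:
                g.add_edge(u, V_END, weight=1)
        return g

    @pytest.mark.parametrize("seed", range(50))
    def test_contract_on_random_digraphs(self, seed):
        rng = random.Random(seed)
        g = self.random_weighted_digraph(rng)
        res = dagify(g)
        assert nx.is_directed_acyclic_graph(res.graph)
        # marker edges never removed
        for u, v in res.removed_edges:
            assert u not in (V_START, V_END) and v not in (V_START, V_END)
        for u, v in g.edges:
            if u in (V_START, V_END) or v in (V_START, V_END):
                assert res.graph.has_edge(u, v)
        # minimality: one threshold lower still leaves a cycle
        if res.k_star >= 1:
            k = res.k_star - 1
            cand = nx.DiGraph()
            cand.add_nodes_from(g.nodes)
            for u, v in g.edges:
                if u in (V_START, V_END) or v in (V_START, V_END) or g[u][v]["weight"] > k:
                    cand.add_edge(u, v)
            assert not nx.is_directed_acyclic_graph(cand)


class TestResolve:
    def test_worked_three_sequence_swap(self):
        # seq0 = seq2: A,B,C in order; seq1: A,C,B
        cols = cols_of(
            {0: 0, 1: 0, 2: 0},  # A -> id 0
            {0: 1, 1: 2, 2: 1},  # B -> id 1
            {0: 2, 1: 1, 2: 2},  # C -> id 2
        )
        trace = resolve(cols)
        assert trace.k_star == 1
        assert trace.removed == {(1, 2)}  # column C loses its site in seq 1
        assert trace.chains[1] == (0, 1)
        assert trace.chains[0] == trace.chains[2] == (0, 1, 2)
        sizes = {c.id: len(c) for c in trace.columns}
        assert sizes == {0: 3, 1: 3, 2: 2}
        assert is_consistent(trace.columns)

    def test_consistent_input_unchanged(self):
        cols = cols_of({0: 0, 1: 0}, {0: 1, 1: 1}, {0: 3, 1: 2})
        trace = resolve(cols)
        assert trace.k_star == 0
        assert not trace.removed
        assert trace.columns == cols

    def test_figure_style_four_column_cycle(self):
        # three sequences arrange A,B,C,D so that exactly one cycle
        # A->D->B->C->A appears and is broken at its weight-1 edge
        cols = cols_of(
            {0: 0, 1: 2, 2: 0},  # A
            {0: 1, 1: 0, 2: 1},  # B (before C in seqs 0,2; after D in seq 1)
            {0: 2, 1: 1, 2: 2},  # C
            {1: 3, 0: 3, 2: 3},  # D
        )
        trace = resolve(cols)
        assert is_consistent(trace.columns)
        # every surviving column still pairs at least two sequences
        assert all(len(c) >= 2 for c in trace.columns)

    def test_empty_input(self):
        trace = resolve(ColumnSet(()))
        assert trace.columns == ColumnSet(())
        assert consistent_columns(ColumnSet(())) == ColumnSet(())

    @pytest.mark.parametrize("seed", range(60))
    def test_output_always_consistent(self, seed):
        rng = random.Random(seed)
        maker = cyclic_column_set if seed % 2 else random_column_set
        cols, lengths = maker(rng)
        out = consistent_columns(cols)
        assert is_consistent(out)
        assert consistency_oracle(out, lengths)

    @pytest.mark.parametrize("seed", range(20))
    def test_idempotent(self, seed):
        rng = random.Random(500 + seed)
        cols, _ = cyclic_column_set(rng)
        once = consistent_columns(cols)
        assert consistent_columns(once) == once

    @pytest.mark.parametrize("seed", range(12))
    def test_sequence_order_independence(self, seed):
        rng = random.Random(900 + seed)
        cols, _ = cyclic_column_set(rng)
        seqs_present = sorted({s for c in cols for s, _ in c.sites})
        baseline = resolve(cols)
        orders = list(permutations(seqs_present))[:6]
        for order in orders:
            other = resolve(cols, _sequence_order=order)
            assert other.removed == baseline.removed
            assert other.columns == baseline.columns

    @pytest.mark.parametrize("seed", range(15))
    def test_site_loss_bound_per_sequence(self, seed):
        rng = random.Random(1300 + seed)
        cols, _ = cyclic_column_set(rng)
        trace = resolve(cols)
        per_seq_cols = {}
        for c in cols:
            for s, _ in c.sites:
                per_seq_cols.setdefault(s, set()).add(c.id)
        for s, chain in trace.chains.items():
            removed_here = {cid for (sq, cid) in trace.removed if sq == s}
            assert len(removed_here) == len(per_seq_cols[s]) - len(chain)
            assert not removed_here & set(chain)
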