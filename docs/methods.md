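# Methods

This note records the model, the algorithmic and numerical choices, and
the limits of what the test suite establishes.

## Site space, columns, consistency

Sequences are modelled as chains of abstract *sites* (*i*, *p*),
partially ordered left to right within each sequence. A multiple
alignment is a partition of the site space whose induced preorder
(sequence order ∪ co-column equivalence, transitively closed) restricts
to the original order on every sequence. A site set is *ambiguous* when
it contains two sites of one sequence; only non-ambiguous sets
(*partial columns*, at most one site per sequence) can be part of an
alignment.

Consistency of a column set is decided on the **succession graph**:
vertices are the columns plus start/end markers; an edge *u* → *v*
exists iff some sequence contains *u* strictly left of *v* and carries
the number of such sequences as weight, counted over *all* ordered
pairs in each sequence, not only adjacent ones. The set is consistent
iff the graph is acyclic; the test suite checks this criterion against
an independent site-level oracle (strongly connected components of the
order-plus-equivalence relation) exhaustively on a 3×3 grid and on
random instances.

## N-local decoding

For word length *N*, all *N*-word occurrences are hashed; for each word
and each in-word offset, the covered sites of all its occurrences are
merged with union-find. This is O(L·N) per level (L = total residue
count) rather than the linear-time construction known for this
clustering; output equivalence with the explicit
relation-plus-transitive-closure definition is what matters and is
asserted against a brute-force oracle. Words never span sequence
boundaries. Case is folded to upper before comparison; ambiguity codes
(X, N, …) are ordinary symbols matched exactly. Union-find
representatives are the smallest site in sequence-major order, making
class enumeration reproducible.

The level sweep stops at the first all-singleton partition (larger N
cannot merge anything), at the longest sequence length, or at an
explicit cap.

## Partition tree and column selection

Successive decodings refine one another, so stacking them yields a
tree; the root (level 0) is the whole site space. Classes that do not
split are kept as chains of distinct nodes. When the deepest decoding
still holds multi-site classes, one level of singleton leaves is
appended so every site terminates a root-to-leaf chain.

Selection takes the **topmost non-ambiguous frontier**: nodes that are
non-ambiguous with an ambiguous parent. A non-ambiguous node below
another non-ambiguous node is never selected (its parent fails the
frontier test), which makes selected columns pairwise disjoint. Two
deliberate choices where the selection rule is under-determined:

* **Singleton frontier classes are discarded** even when `s_min` would
  admit them — a one-site column constrains nothing.
* `s_min` defaults to **6** in the CLI, the spanning threshold that
  behaves best across benchmark categories; it is freely overridable
  and must be ≥ 2.

## Consistency resolution

Two steps, both deterministic.

**dagify.** Keep inter-column edges of weight > *k* for the smallest
*k\** giving a DAG; edges incident to the start/end markers are never
dropped. *k\** is found by scanning *k* = 0, 1, 2, … (weights are
integer sequence counts), so minimality is exact: one threshold lower
always leaves a cycle. **We admit *k\** = 0**: an already-acyclic graph
is left untouched. Filtering weight-1 edges out of an acyclic graph
would only weaken the induced order and cost sites for no benefit; the
formula that starts at *k* > 0 presumes a cycle exists. After
filtering, columns without predecessors (successors) are reconnected to
the start (end) marker so every column lies on a start-to-end path.

**resolve.** The kept DAG is closed transitively once (O(V·E), fine at
desk scale). For each sequence *s*, form the graph on the columns
touching *s* (plus markers) with an edge (*u*, *v*) iff it is in the
closure *and* *u* precedes *v* in *s*; its topological order is the
sequence's own left-to-right order, so one dynamic-programming pass
finds a maximum-length start-to-end chain. Every column off the chain
loses its site in *s*. Because each sequence's computation reads only
the closed DAG and its own site order, the removal set is independent
of processing order (asserted under permutations).

**Tie-breaking** among equal-length chains (the rule is otherwise
under-determined): prefer the chain with the larger total column size
(site count as input to the resolution, so that the criterion is
order-independent), then the lexicographically smallest column-id
sequence. All three criteria are prefix-optimal, so the per-node greedy
DP is exact. Equally long chains are genuinely tied; a different
tie-break would be equally valid and may differ from other
implementations on tied instances.

**Pruning.** Columns reduced below two sites are dropped. The `s_min`
threshold is *not* re-applied after trimming: a trimmed column that
still pairs two sequences remains an informative anchor.

The succession graph of the output is acyclic by construction (every
surviving adjacency embeds in the closed DAG); the implementation
asserts it after every resolution, and the suite fuzzes the claim
together with idempotence and the fixed-point property on consistent
input.

## Anchor segments and formats

Columns are expanded pairwise into **maximal diagonal runs**: for a
sequence pair, offsets *t* = 0 … l−1 with both positions co-member of
*some* column (consecutive offsets may be supported by different
columns). Weights: `length10` = 10·length (ClustalW / DIALIGN);
`tcoffee_uniform` = 100·M for every constraint, M = number of
sequences. Writers emit 1-based coordinates in FASTA input order and
are byte-deterministic. The BALLAST dialect (header naming the query
sequence, then `id_a id_b start_a start_b length weight` records) is
this package's frozen best effort — the grammar DbClustal actually
consumes is not publicly specified — and is isolated in one function.

## Scoring

SP = percentage of residue pairs in reference core columns reproduced
by the test alignment; TC = percentage of core columns whose full
residue set sits intact in one test column (one misplaced residue
zeroes the column). Specificity swaps the roles: among test-aligned
pairs (columns restricted to core residues), the share that the
reference confirms. Core columns are a plain 1-based index mask (or
"all"); benchmark annotation formats are out of scope. Gap handling
under a mask: a masked column counts in the TC denominator regardless
of gap content, and a masked column with ≤ 1 residue is vacuously
intact. This rule is a documented choice, not an inference about other
tools' behaviour.

## Synthetic fixtures

The generator plants exact motifs into i.i.d. background over a chosen
alphabet. Defaults: 4 sequences of 40–60 residues over the 20-letter
amino-acid alphabet with 8-residue motifs — short enough that the word
sweep is instant, long enough that an 8-mer (20⁻⁸ per background
window) essentially never recurs by chance. Backgrounds are re-sampled
(≤ 50 retries) if they recreate a catalogue motif; the ground truth is
computed from the final sequences' actual planted coordinates. Swap
directives transpose two motifs' order in chosen sequences,
manufacturing succession cycles whose minority edges carry weight equal
to the number of swapped carriers.

The generator does **not** emulate substitutions or indels inside
motifs, compositional bias, or diverged homology. A green recovery
test therefore establishes that the machinery is correct on exact
repeats — not that the detector performs well on real protein
families, which is a property of benchmarks outside this package's
scope.

## Degenerate inputs and edge behaviour

* Single-sequence input parses; selection returns no multi-sequence
  columns (not an error).
* Empty column sets flow through every stage (empty graph, empty
  output, empty anchor files).
* An all-gap or single-residue alignment column contributes no pairs;
  scorers raise a distinct error when a denominator is empty rather
  than returning 0/0 silently.
* Duplicate identifiers, gap characters in unaligned input, and
  out-of-alphabet residues each raise their own exception type.

## Known limitations

* The feedback-arc heuristic is the simple weight threshold; it can
  drop more edges than a minimum feedback arc set would.
* Contradicting columns are trimmed, never split into coherently
  behaving sub-columns.
* The word clustering is exact-match only; no spaced seeds or
  mismatch tolerance beyond what transitive chaining produces.
* Downstream aligners are never invoked; format correctness is
  certified by golden files only.
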