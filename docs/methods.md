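# Methods

## Reaction graphs

A reaction record is `R = (I, E, O)`: substrate compounds, one or more
EC-classified enzymes, product compounds, plus a reversibility flag.
Graph nodes are reaction *instances* keyed by
`(reaction_id, direction, enzyme)`: reversible reactions expand into a
forward and a backward node (with substrate/product roles swapped), and
each catalyzing enzyme gets its own node. The arc rule is purely
metabolite sharing — `(u, v)` is an arc iff `outputs(u) ∩ inputs(v) ≠ ∅`
and `u ≠ v`. Consequences worth noting:

* The forward and backward instances of a reversible reaction always
  form a 2-cycle (each one's outputs are the other's inputs), so they
  always land in the same building block.
* Enzyme copies of the same irreversible reaction are *parallel*
  nodes: identical inputs/outputs but no arc between them, so a broken
  cycle can leave two singleton blocks carrying the same reaction id.
  No special-casing is applied; one uniform arc rule governs all pairs.
* Self-loops (a reaction consuming its own product) are not stored:
  they cannot affect strong connectivity or the condensation.
* By default no compound is excluded from the arc rule. An optional
  exclusion list exists for currency metabolites (ATP, H2O, ...), whose
  ubiquity otherwise welds unrelated reactions into one block; it is
  off by default so that the default behaviour is the plain definition.

Stoichiometry and flux are deliberately out of scope — the
representation is topological.

## Building blocks and metabolic DAGs

MBBs are the strongly connected components of the reaction graph,
computed with an iterative Tarjan (explicit work stack, so pathway-sized
recursion depth is a non-issue) that visits nodes in sorted key order —
component numbering is therefore reproducible run-to-run, instead of
depending on input order. The m-DAG contracts each MBB to one node; two
blocks are joined iff some reaction-graph arc crosses them. The
condensation of an SCC partition is acyclic by construction; the
implementation still verifies acyclicity and rejects non-SCC partitions.

Topology is read on the *undirected* shadow of the m-DAG: a cut node
(bridge) is a node (arc) whose removal increases the number of weakly
connected components. The directed reading would call the interior of
every directed path a non-cut node, which contradicts the intended
"removal disconnects the pathway" semantics. Essential reactions are
the cut nodes that are single-reaction blocks. "Single-reaction" means
a single graph node: a reversible reaction's two-node block does not
count as a singleton, while a KGML reaction element naming two reaction
ids yields one node and does. Two block-size conventions are exposed,
because both are used in practice: `n_nodes` (graph nodes; forward and
backward instances count separately) and `n_reaction_enzyme_pairs`
(distinct reaction-enzyme pairs, direction-insensitive — a two-enzyme
reaction counts twice, its reverse adds nothing).

The **reference pathway** is the union of all input pathways' reaction
instances, with arcs recomputed from scratch; organisms disagreeing on
a reaction's compound sets are rejected as inconsistent input. Because
each organism's records are a subset of the union's, every organism MBB
nests inside exactly one reference MBB (verified as a property test).
Per-group (kingdom) references default to the same union-then-condense
construction restricted to the group; an alternate `maximal-mbb`
strategy instead keeps each group's inclusion-maximal blocks (per pivot
class when a pivot is supplied) and connects them over the union graph.
That construction does not guarantee acyclicity when maximal blocks
overlap, so a cyclic result raises rather than silently shipping a
non-DAG.

## Hierarchical identifiers

The registry anchors identifiers to the reference m-DAG: its blocks get
the base integers `0, 1, ...` in canonical component order and are
seeded into the known-block list, so a block equal to a reference block
reuses the reference identifier. A block strictly inside a reference
block becomes a dotted child (`<parent>.<k>`, `k` counting children
0-based) of its *smallest* already-registered superset, ties broken by
identifier; when a later registration strictly contains existing
entries, those entries are re-parented under it and their subtrees
re-prefixed, the change propagating to every m-DAG labeled so far. A
block incomparable with every reference block gets a fresh base
identifier.

Two properties hold and are property-tested over randomized
registration orders: equal reaction sets always share one identifier,
and for *nested* (laminar) families, containment is exactly identifier
prefixing, with the prefix partial order invariant under registration
order (the literal strings are not — they depend on arrival order, so
reproducing any particular printed identifier is a non-goal). For
non-laminar families full prefix soundness is unattainable in
principle: prefixes form a tree while set containment is an arbitrary
partial order, so a block contained in two incomparable blocks can
extend only one of their identifiers.

## Similarity stack

* Enzymes: `S(e, e') = (length of common fully-specified EC prefix)/4`,
  values in {0, 0.25, 0.5, 0.75, 1}. A wildcard level matches nothing —
  including another wildcard — so the unknown-enzyme placeholder
  `-.-.-.-` scores 0 even against itself; unknown annotation never
  manufactures similarity.
* Compound sets, block reaction sets and m-DAG block sets all compare
  by maximum-weight bipartite matching (Hungarian assignment via
  `scipy.optimize.linear_sum_assignment`) divided by the larger side's
  size; unmatched elements contribute 0. This makes every level
  symmetric, bounded in [0, 1], and equal to 1 on identical inputs.
* Reactions: `SimReact = w_e·SimEnz + w_i·SimComp(inputs) +
  w_o·SimComp(outputs)` with defaults `w_e = 0.4, w_i = w_o = 0.3`
  (favouring enzyme function slightly over chemistry). Weights must sum
  to 1 unless explicitly overridden, since only then are scores
  probabilities-like. Backward nodes compare with their
  direction-resolved input/output sets, and multi-enzyme reactions were
  already expanded upstream, so each comparison sees exactly one EC.
* Compound similarity is a pluggable contract: exact token identity by
  default, or a precomputed symmetric table (e.g. the output of a
  chemical-substructure similarity tool) with a configurable default
  (0) for absent pairs; self-similarity is always 1. Computing chemical
  similarity itself is out of scope.
* Optionally the m-DAG matching is class-restricted around a pivot
  reaction (blocks upstream of the pivot block, the pivot block, blocks
  downstream, everything else): cross-class weights are zeroed before
  matching. This encodes the biological prior that blocks feeding a
  conserved step should not be credited for resembling blocks fed by
  it. Off by default.

The distance is `d = √(1 − score²)`: 0 for identical m-DAGs, 1 for
score 0, strictly decreasing in between. Scores are clamped into [0, 1]
with a 1e-9 tolerance for floating-point excursions; anything further
out raises.

## Clustering

UPGMA over the pairwise distance matrix, with inter-cluster means
computed directly from the raw matrix over all leaf pairs (the exact
unweighted average-linkage definition; no Lance–Williams shortcut, so
each step is transparently the definition). Ties on the minimal mean
break on the label-sorted cluster pair, purely for reproducibility.
Merge heights are non-decreasing; the Newick rendering places leaves at
height 0 and uses height differences as branch lengths, giving an
ultrametric tree whose root age equals the final merge height. Group
tags ride along as leaf-label suffixes for post-hoc coloring and play
no role in the clustering itself.

## Synthetic generator

`generate_reference` builds pathways whose block structure is known by
construction: each intended block is a directed compound cycle
(reaction *i* produces reaction *i+1*'s substrate, the last closing the
loop) — the minimal certified strongly connected component — and
single-reaction irreversible linkers chain consecutive blocks, giving
guaranteed singleton cut nodes. Compound tokens are namespaced per
block so no accidental cross-block arcs arise. Defaults (three blocks
of 3–5 reactions, a couple of linkers, half the reactions reversible, a
small multi-enzyme fraction) mirror the shape of real reference
pathways: few large blocks joined by essential singletons.
`derive_organism` subsets the reference's records at a configurable
drop fraction (linkers protected by default), which guarantees the
organism-in-reference containment that real pathway databases exhibit.

What the generator does *not* emulate: real reaction chemistry, EC
frequency distributions, compound-similarity structure, or annotation
noise. Passing tests therefore certify the graph machinery, the
labeling semantics and the metric/clustering behaviour — not that any
particular biological claim holds on a given database snapshot.

## Numerical and scale choices

Tests exercise the machinery against independent oracles at sizes where
the oracles are exact and fast: brute-force mutual reachability on
random digraphs up to 50 nodes, exhaustive node/arc-removal topology
checks up to 30 blocks, permutation-enumeration matching oracles up to
side 6, scipy average linkage on tie-free continuous matrices up to 8
leaves, and 20–50-seed synthetic corpora. These sizes make every oracle
comparison exact while keeping the default suite fast; the library
itself has no such limits (the assignment solver and SCC are polynomial
and routinely handle pathway-scale inputs).

Degenerate inputs are rejected loudly rather than coerced: empty
reaction sets, empty compound sets, malformed EC codes, asymmetric or
negative distance matrices, partitions that do not cover the graph, and
similarity scores outside [0, 1] (beyond the 1e-9 float tolerance) all
raise.
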