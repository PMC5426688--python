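"""Metabolic building blocks and metabolic DAGs.

A *metabolic building block* (MBB) is a strongly connected component of
a reaction graph: a maximal set of reaction instances that are mutually
reachable through shared metabolites.  Contracting every MBB to a single
node yields the *m-DAG* — an acyclic condensation that exposes the
backbone topology of the pathway: cut nodes, bridges, isolated blocks
and linear chains.  Single-reaction MBBs that are cut nodes are the
pathway's *essential reactions*: removing one disconnects the m-DAG.

The strongly-connected-component computation is an iterative Tarjan
(explicit stack, so deep graphs cannot overflow Python's recursion
limit) visiting nodes in sorted key order, which makes component
numbering reproducible run-to-run.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from .errors import ValidationError
from .reaction_graph import FORWARD, NodeKey, ReactionGraph, ReactionNode, graph_from_nodes

logger = logging.getLogger(__name__)

__all__ = [
    "MBB",
    "MDag",
    "TopologyReport",
    "ClassPartition",
    "strongly_connected_components",
    "condense",
    "build_mdag",
    "topology_report",
    "build_reference_graph",
    "classify_mbbs",
    "kingdom_reference",
    "occurrence_table",
    "discriminating_mbbs",
    "discriminating_reactions",
]

TO_PIVOT = "to_pivot"
PIVOT = "pivot"
FROM_PIVOT = "from_pivot"
OTHER = "other_singleton"


@dataclass(eq=False)
class MBB:
    """A metabolic building block: one strongly connected component.

    ``member_nodes`` holds reaction-graph node keys, i.e.
    (reaction_id, direction, enzyme) triples.  Two counting conventions
    coexist in practice and both are exposed:

    * :attr:`n_nodes` — graph nodes, where a reversible reaction counts
      its forward and backward instances separately;
    * :attr:`n_reaction_enzyme_pairs` — distinct (reaction, enzyme)
      pairs, direction-insensitive, so a reaction catalyzed by two
      enzymes counts twice but its reverse does not add a unit.
    """

    member_nodes: frozenset[NodeKey]
    identifier: str | None = None

    def __post_init__(self) -> None:
        if not self.member_nodes:
            raise ValidationError("an MBB cannot be empty")

    @property
    def reaction_ids(self) -> frozenset[str]:
        return frozenset(k[0] for k in self.member_nodes)

    @property
    def reaction_enzyme_pairs(self) -> frozenset[tuple[str, str]]:
        return frozenset((k[0], k[2]) for k in self.member_nodes)

    @property
    def n_nodes(self) -> int:
        return len(self.member_nodes)

    @property
    def n_reaction_enzyme_pairs(self) -> int:
        return len(self.reaction_enzyme_pairs)

    @property
    def is_singleton(self) -> bool:
        """True when the block consists of a single reaction instance."""
        return len(self.member_nodes) == 1

    @property
    def sort_key(self) -> NodeKey:
        return min(self.member_nodes)

    def __repr__(self) -> str:  # pragma: no cover
        ident = self.identifier or "?"
        return f"MBB({ident}, {sorted(self.reaction_ids)})"


@dataclass(eq=False)
class MDag:
    """The condensation of a reaction graph: one node per MBB, acyclic."""

    mbbs: list[MBB]
    arcs: set[tuple[MBB, MBB]]
    source_organism: str = ""
    group: str = ""

    def sorted_mbbs(self) -> list[MBB]:
        return sorted(self.mbbs, key=lambda m: m.sort_key)

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.mbbs)
        g.add_edges_from(self.arcs)
        return g

    def mbb_of_reaction(self, reaction_id: str) -> list[MBB]:
        return [m for m in self.mbbs if reaction_id in m.reaction_ids]

    def canonical_form(self):
        """Structural identity: block node sets, identifiers and arcs.

        The organism tag is metadata and does not enter equality.
        """
        order = self.sorted_mbbs()
        index = {id(m): i for i, m in enumerate(order)}
        return (
            tuple((frozenset(m.member_nodes), m.identifier) for m in order),
            frozenset((index[id(a)], index[id(b)]) for a, b in self.arcs),
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, MDag):
            return NotImplemented
        return self.canonical_form() == other.canonical_form()

    def __hash__(self) -> int:
        return id(self)


def strongly_connected_components(graph: ReactionGraph) -> list[MBB]:
    """Partition the reaction graph into its MBBs.

    Iterative Tarjan in O(|R| + |E|); nodes are visited in sorted key
    order and components are emitted in completion order, so the result
    is deterministic for identical inputs.
    """
    succ: dict[NodeKey, list[NodeKey]] = {k: [] for k in graph.node_keys}
    for u, v in sorted(graph.arcs):
        succ[u].append(v)

    index: dict[NodeKey, int] = {}
    lowlink: dict[NodeKey, int] = {}
    on_stack: set[NodeKey] = set()
    stack: list[NodeKey] = []
    components: list[MBB] = []
    counter = 0

    for root in graph.node_keys:
        if root in index:
            continue
        # Each work item: (node, iterator over successors).
        work = [(root, iter(succ[root]))]
        index[root] = lowlink[root] = counter
        counter += 1
        stack.append(root)
        on_stack.add(root)
        while work:
            node, it = work[-1]
            advanced = False
            for child in it:
                if child not in index:
                    index[child] = lowlink[child] = counter
                    counter += 1
                    stack.append(child)
                    on_stack.add(child)
                    work.append((child, iter(succ[child])))
                    advanced = True
                    break
                if child in on_stack:
                    lowlink[node] = min(lowlink[node], index[child])
            if advanced:
                continue
            work.pop()
            if work:
                parent = work[-1][0]
                lowlink[parent] = min(lowlink[parent], lowlink[node])
            if lowlink[node] == index[node]:
                members = []
                while True:
                    w = stack.pop()
                    on_stack.discard(w)
                    members.append(w)
                    if w == node:
                        break
                components.append(MBB(member_nodes=frozenset(members)))
    return components


def condense(graph: ReactionGraph, partition: Sequence[MBB]) -> MDag:
    """Contract each MBB of ``partition`` to one node (the m-DAG).

    There is an arc between two blocks iff some reaction-graph arc runs
    from a member of one to a member of the other.  The result is
    acyclic whenever ``partition`` is the SCC partition.
    """
    owner: dict[NodeKey, MBB] = {}
    for mbb in partition:
        for key in mbb.member_nodes:
            if key in owner:
                raise ValidationError(f"node {key} appears in two blocks")
            owner[key] = mbb
    missing = set(graph.nodes) - set(owner)
    extra = set(owner) - set(graph.nodes)
    if missing or extra:
        raise ValidationError(
            f"partition does not cover the graph (missing={len(missing)}, extra={len(extra)})"
        )

    arcs: set[tuple[MBB, MBB]] = set()
    for u, v in graph.arcs:
        a, b = owner[u], owner[v]
        if a is not b:
            arcs.add((a, b))

    mdag = MDag(mbbs=list(partition), arcs=arcs,
                source_organism=graph.organism_id, group=graph.group)
    g = mdag.to_networkx()
    if not nx.is_directed_acyclic_graph(g):
        raise ValidationError("condensation is not acyclic: partition was not the SCC partition")
    return mdag


def build_mdag(graph: ReactionGraph) -> MDag:
    """Convenience: SCC partition + condensation in one call."""
    return condense(graph, strongly_connected_components(graph))


@dataclass
class TopologyReport:
    """Structural features of an m-DAG.

    Connectivity is read on the underlying undirected graph: a cut node
    (bridge) is a node (arc) whose removal increases the number of weakly
    connected components.  Essential reactions are the single-reaction
    MBBs among the cut nodes.  Linear paths are maximal directed chains
    of singleton MBBs with in- and out-degree at most 1.
    """

    cut_nodes: set[MBB]
    essential_reactions: set[MBB]
    bridges: set[tuple[MBB, MBB]]
    isolated: set[MBB]
    linear_paths: list[list[MBB]]


def topology_report(mdag: MDag) -> TopologyReport:
    directed = mdag.to_networkx()
    und = directed.to_undirected()

    cut_nodes = set(nx.articulation_points(und)) if und.number_of_nodes() else set()
    essential = {m for m in cut_nodes if m.is_singleton}
    bridge_und = set(nx.bridges(und)) if und.number_of_nodes() else set()
    # Report bridges with their original (directed) orientation.
    bridges = {
        (a, b)
        for a, b in mdag.arcs
        if (a, b) in bridge_und or (b, a) in bridge_und
    }
    isolated = {m for m in mdag.mbbs if und.degree(m) == 0}

    chain_nodes = {
        m
        for m in mdag.mbbs
        if m.is_singleton
        and directed.in_degree(m) <= 1
        and directed.out_degree(m) <= 1
    }
    paths: list[list[MBB]] = []
    seen: set[MBB] = set()
    for m in sorted(chain_nodes, key=lambda m: m.sort_key):
        if m in seen:
            continue
        preds = [p for p in directed.predecessors(m) if p in chain_nodes]
        if preds:  # not a chain head
            continue
        chain = [m]
        seen.add(m)
        cur = m
        while True:
            nxt = [s for s in directed.successors(cur) if s in chain_nodes and s not in seen]
            if not nxt:
                break
            cur = nxt[0]
            chain.append(cur)
            seen.add(cur)
        if len(chain) > 1:
            paths.append(chain)
    return TopologyReport(
        cut_nodes=cut_nodes,
        essential_reactions=essential,
        bridges=bridges,
        isolated=isolated,
        linear_paths=paths,
    )


def build_reference_graph(
    graphs: Iterable[ReactionGraph],
    organism_id: str = "reference",
    group: str = "",
    excluded_compounds: Iterable[str] = (),
) -> ReactionGraph:
    """Union of several organisms' pathways: the reference pathway.

    Node sets are united (so enzyme lists unite and reversibility is
    OR-ed at the node level) and arcs are recomputed from scratch by the
    metabolite-sharing rule.  Two organisms disagreeing on the substrate
    or product set of the same reaction are an inconsistency and raise.
    """
    graphs = list(graphs)
    if not graphs:
        raise ValidationError("cannot build a reference from zero graphs")

    nodes: dict[NodeKey, ReactionNode] = {}
    by_rid_dir: dict[tuple[str, str], ReactionNode] = {}
    for g in graphs:
        for key, node in g.nodes.items():
            prev = nodes.get(key)
            if prev is not None and (prev.inputs != node.inputs or prev.outputs != node.outputs):
                raise ValidationError(
                    f"inconsistent compound sets for reaction node {key} across organisms"
                )
            witness = by_rid_dir.get((node.reaction_id, node.direction))
            if witness is not None and (
                witness.inputs != node.inputs or witness.outputs != node.outputs
            ):
                raise ValidationError(
                    f"inconsistent substrate/product sets for reaction {node.reaction_id}"
                )
            nodes[key] = node
            by_rid_dir[(node.reaction_id, node.direction)] = node

    return graph_from_nodes(
        nodes, organism_id=organism_id, group=group, excluded_compounds=excluded_compounds
    )


@dataclass
class ClassPartition:
    """Three-way split of an m-DAG's blocks around a pivot reaction.

    Blocks with a direct arc into the pivot's block are upstream
    (``to_pivot``), those with a direct arc from it are downstream
    (``from_pivot``); everything else, including the remaining
    single-reaction blocks, is ``other_singleton``.
    """

    pivot_reaction: str
    class_of: dict[MBB, str]


def classify_mbbs(mdag: MDag, pivot_reaction: str) -> ClassPartition:
    hosts = mdag.mbb_of_reaction(pivot_reaction)
    class_of: dict[MBB, str] = {m: OTHER for m in mdag.mbbs}
    if len(hosts) != 1:
        warnings.warn(
            f"pivot reaction {pivot_reaction!r} present in {len(hosts)} MBBs; "
            "no class structure assigned",
            stacklevel=2,
        )
        return ClassPartition(pivot_reaction=pivot_reaction, class_of=class_of)
    pivot = hosts[0]
    class_of[pivot] = PIVOT
    for a, b in mdag.arcs:
        if b is pivot and class_of[a] is OTHER:
            class_of[a] = TO_PIVOT
        elif a is pivot and class_of[b] is OTHER:
            class_of[b] = FROM_PIVOT
    return ClassPartition(pivot_reaction=pivot_reaction, class_of=class_of)


def kingdom_reference(
    graphs: Iterable[ReactionGraph],
    group: str,
    strategy: str = "union",
    pivot_reaction: str | None = None,
    excluded_compounds: Iterable[str] = (),
) -> MDag:
    """Reference m-DAG of one taxonomic group.

    ``strategy="union"`` (default) reuses the reference-pathway
    construction on the group's organisms: union the pathways, then
    condense.  ``strategy="maximal-mbb"`` instead collects every MBB of
    every organism in the group, keeps the maximal ones under set
    inclusion (per pivot class when ``pivot_reaction`` is given), and
    connects them by the condensation arc rule over the union graph.
    """
    members = [g for g in graphs if g.group == group]
    if not members:
        raise ValidationError(f"no organism carries group {group!r}")

    union = build_reference_graph(
        members, organism_id=f"reference:{group}", group=group,
        excluded_compounds=excluded_compounds,
    )
    if strategy == "union":
        return build_mdag(union)
    if strategy != "maximal-mbb":
        raise ValueError(f"unknown kingdom strategy {strategy!r}")

    # Collect (class, member-node set) for every organism MBB.
    tagged: set[tuple[str, frozenset[NodeKey]]] = set()
    for g in members:
        md = build_mdag(g)
        if pivot_reaction is not None:
            classes = classify_mbbs(md, pivot_reaction).class_of
        else:
            classes = {m: OTHER for m in md.mbbs}
        for m in md.mbbs:
            tagged.add((classes[m], m.member_nodes))

    keep: list[tuple[str, frozenset[NodeKey]]] = []
    for cls, nodes in tagged:
        if not any(
            cls == other_cls and nodes < other_nodes
            for other_cls, other_nodes in tagged
        ):
            keep.append((cls, nodes))
    mbbs = [MBB(member_nodes=nodes) for _, nodes in sorted(keep, key=lambda t: min(t[1]))]

    arcs: set[tuple[MBB, MBB]] = set()
    for a in mbbs:
        for b in mbbs:
            if a is b:
                continue
            if any(
                (u, v) in union.arcs
                for u in a.member_nodes - b.member_nodes
                for v in b.member_nodes - a.member_nodes
            ):
                arcs.add((a, b))
    mdag = MDag(mbbs=mbbs, arcs=arcs, source_organism=f"reference:{group}", group=group)
    if not nx.is_directed_acyclic_graph(mdag.to_networkx()):
        raise ValidationError(
            "maximal-mbb kingdom reference is cyclic: the group's maximal blocks overlap"
        )
    return mdag


def occurrence_table(items_by_group: Mapping[str, Iterable[str]]) -> pd.DataFrame:
    """Boolean presence table: rows are item identifiers, columns groups."""
    groups = sorted(items_by_group)
    universe = sorted({i for items in items_by_group.values() for i in items})
    data = {
        g: [i in set(items_by_group[g]) for i in universe] for g in groups
    }
    return pd.DataFrame(data, index=universe)


def discriminating_mbbs(occurrence: pd.DataFrame) -> pd.DataFrame:
    """Rows of the occurrence table absent from at least one group.

    A block present everywhere carries no taxonomic signal; the rest are
    the blocks that discriminate the groups.
    """
    if occurrence.empty:
        return occurrence.copy()
    return occurrence.loc[~occurrence.all(axis=1)].copy()


def discriminating_reactions(occurrence: pd.DataFrame) -> pd.DataFrame:
    """Rows present in exactly one group: group-diagnostic reactions.

    If such a reaction is observed in an organism, the organism's group
    is determined.
    """
    if occurrence.empty:
        return occurrence.copy()
    return occurrence.loc[occurrence.sum(axis=1) == 1].copy()
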