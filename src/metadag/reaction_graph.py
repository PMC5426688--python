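"""Reaction graphs: the directed-graph model of a metabolic pathway.

A pathway is a set of chemical reactions, each one a triple
(substrates, enzyme, products).  The reaction graph has one node per
reaction *instance* — a reversible reaction contributes a forward and a
backward node, and a reaction catalyzed by several enzymes contributes
one node per enzyme — and an arc from node ``u`` to node ``v`` whenever
some metabolite produced by ``u`` is consumed by ``v``.  Metabolites are
not nodes themselves; they only induce the arcs.

All downstream machinery (strongly connected components, condensation,
labeling, similarity) operates on these graphs.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from functools import total_ordering
from typing import Iterable, Mapping

import networkx as nx

from .errors import ValidationError

__all__ = [
    "ECNumber",
    "ReactionNode",
    "ReactionGraph",
    "expand_reaction",
    "build_reaction_graph",
    "graph_from_nodes",
    "UNKNOWN_EC",
]

_EC_RE = re.compile(r"^(\d+|-)\.(\d+|-)\.(\d+|-)\.(\d+|-)$")

#: Placeholder for reactions whose catalyzing enzyme is unknown.  Under
#: the wildcard rule its similarity to anything, itself included, is 0.
UNKNOWN_EC = "-.-.-.-"


@total_ordering
@dataclass(frozen=True)
class ECNumber:
    """A four-level Enzyme Commission code ``d1.d2.d3.d4``.

    Each level is a positive integer or the wildcard ``-``; wildcards
    are only meaningful as a suffix (e.g. ``1.2.1.-``), but any level
    may be a dash so that the fully unknown placeholder ``-.-.-.-``
    parses.
    """

    levels: tuple[str, str, str, str]

    @classmethod
    def parse(cls, text: str) -> "ECNumber":
        text = text.strip()
        if text.lower().startswith("ec:"):
            text = text[3:]
        m = _EC_RE.match(text)
        if m is None:
            raise ValidationError(f"malformed EC number: {text!r}")
        return cls(levels=m.groups())  # type: ignore[arg-type]

    def __str__(self) -> str:
        return ".".join(self.levels)

    def __lt__(self, other: "ECNumber") -> bool:
        return self.levels < other.levels

    def common_prefix_length(self, other: "ECNumber") -> int:
        """Length of the common fully-specified prefix with ``other``.

        A wildcard level matches nothing, not even another wildcard.
        """
        n = 0
        for a, b in zip(self.levels, other.levels):
            if a == "-" or b == "-" or a != b:
                break
            n += 1
        return n


# A node is keyed by (reaction_id, direction, enzyme string); the key is
# what graphs, MBBs and the labeling registry store.
NodeKey = tuple[str, str, str]

FORWARD = "forward"
BACKWARD = "backward"


@dataclass(frozen=True)
class ReactionNode:
    """One reaction instance: a reaction in one direction under one enzyme."""

    reaction_id: str
    direction: str  # FORWARD or BACKWARD
    enzyme: ECNumber
    inputs: frozenset[str]
    outputs: frozenset[str]

    @property
    def key(self) -> NodeKey:
        return (self.reaction_id, self.direction, str(self.enzyme))

    def __post_init__(self) -> None:
        if self.direction not in (FORWARD, BACKWARD):
            raise ValidationError(f"bad direction {self.direction!r}")


@dataclass
class ReactionGraph:
    """The directed reaction graph G = (R, E) of one pathway.

    ``arcs`` holds ordered pairs of node keys.  The arc rule is purely
    metabolite-sharing: (u, v) is an arc iff u's outputs intersect v's
    inputs (after removing any excluded currency compounds) and u != v.
    Self-loops are never stored — they cannot affect strongly connected
    components or the condensation.
    """

    organism_id: str = ""
    group: str = ""
    nodes: dict[NodeKey, ReactionNode] = field(default_factory=dict)
    arcs: set[tuple[NodeKey, NodeKey]] = field(default_factory=set)

    @property
    def node_keys(self) -> list[NodeKey]:
        return sorted(self.nodes)

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.node_keys)
        g.add_edges_from(sorted(self.arcs))
        return g

    def reaction_ids(self) -> set[str]:
        return {k[0] for k in self.nodes}


def expand_reaction(record) -> list[ReactionNode]:
    """Expand one reaction record into its graph nodes.

    One node per catalyzing enzyme; reversible reactions additionally get
    a backward node per enzyme with substrate and product sets swapped.
    The result has ``len(ec_numbers) * (2 if reversible else 1)`` nodes.
    """
    subs = frozenset(record.substrates)
    prods = frozenset(record.products)
    nodes = []
    for ec in record.ec_numbers:
        enzyme = ec if isinstance(ec, ECNumber) else ECNumber.parse(ec)
        nodes.append(
            ReactionNode(record.reaction_id, FORWARD, enzyme, subs, prods)
        )
        if record.reversible:
            nodes.append(
                ReactionNode(record.reaction_id, BACKWARD, enzyme, prods, subs)
            )
    return nodes


def build_reaction_graph(
    records: Iterable,
    organism_id: str = "",
    group: str = "",
    excluded_compounds: Iterable[str] = (),
) -> ReactionGraph:
    """Build the reaction graph of a pathway.

    Parameters
    ----------
    records
        Reaction records (see :mod:`metadag.io_formats`).
    organism_id, group
        Optional organism and taxon tags carried on the graph.
    excluded_compounds
        Compounds ignored when evaluating the arc rule (e.g. currency
        metabolites such as ATP or water).  Empty by default: by default
        every metabolite counts.

    The node ordering is canonical (sorted by node key) so that component
    numbering downstream is reproducible run-to-run.
    """
    records = list(records)
    if not records:
        raise ValidationError("cannot build a reaction graph from zero reactions")

    nodes: dict[NodeKey, ReactionNode] = {}
    for rec in records:
        for node in expand_reaction(rec):
            if node.key in nodes:
                raise ValidationError(f"duplicate reaction node {node.key}")
            nodes[node.key] = node
    return graph_from_nodes(
        nodes,
        organism_id=organism_id,
        group=group,
        excluded_compounds=excluded_compounds,
    )


def graph_from_nodes(
    nodes: Mapping[NodeKey, ReactionNode],
    organism_id: str = "",
    group: str = "",
    excluded_compounds: Iterable[str] = (),
) -> ReactionGraph:
    """Assemble a reaction graph from pre-expanded nodes (arc rule applied)."""
    if not nodes:
        raise ValidationError("cannot build a reaction graph from zero nodes")
    excluded = frozenset(excluded_compounds)
    ordered = {k: nodes[k] for k in sorted(nodes)}

    # Index nodes by consumed compound so arc construction is
    # O(nodes x compounds) rather than all-pairs.
    consumers: dict[str, list[NodeKey]] = {}
    for key, node in ordered.items():
        for c in node.inputs - excluded:
            consumers.setdefault(c, []).append(key)

    arcs: set[tuple[NodeKey, NodeKey]] = set()
    for ukey, unode in ordered.items():
        for c in unode.outputs - excluded:
            for vkey in consumers.get(c, ()):
                if vkey != ukey:
                    arcs.add((ukey, vkey))

    return ReactionGraph(organism_id=organism_id, group=group, nodes=ordered, arcs=arcs)
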