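"""Hierarchical, comparable identifiers for metabolic building blocks.

Identifiers are anchored to the reference m-DAG (the condensation of the
union of all input pathways): its blocks receive the base integers
``"0", "1", ...`` in canonical component order.  Every block seen
afterwards is registered against the growing MBB list:

* a block whose reaction set equals a registered one gets the same
  identifier;
* a block strictly contained in a registered one gets a dotted child
  identifier under its *smallest* registered superset, so containment
  shows up as identifier-prefix structure (a block labeled ``32.0.0.0``
  sits inside the reference block ``32``);
* when a newly registered block strictly contains previously registered
  entries, those entries (and their subset trees) are re-parented under
  it and re-prefixed, and the change propagates to every m-DAG labeled
  so far through the registry;
* a block incomparable with everything known gets a fresh base
  identifier.

The absolute identifier strings depend on registration order; the
prefix partial order between them does not (for nested families).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from .errors import ValidationError
from .mdag import MBB, MDag
from .reaction_graph import NodeKey

__all__ = ["RegistryEntry", "MBBRegistry", "init_registry", "assign_identifier", "relabel_mdag"]


@dataclass(eq=False)
class RegistryEntry:
    identifier: str
    nodes: frozenset[NodeKey]
    parent: "RegistryEntry | None" = None
    children: list["RegistryEntry"] = field(default_factory=list)
    is_reference: bool = False
    # Monotone child counter: identifiers stay unique even after a child
    # is re-parented away.
    _next_child: int = 0
    # MBB instances labeled with this entry, updated on re-prefixing.
    instances: list[MBB] = field(default_factory=list)

    def next_child_identifier(self) -> str:
        ident = f"{self.identifier}.{self._next_child}"
        self._next_child += 1
        return ident


def _is_dotted_prefix(p: str, q: str) -> bool:
    """True when identifier ``p`` is a proper-or-equal dotted prefix of ``q``."""
    pp, qq = p.split("."), q.split(".")
    return len(pp) <= len(qq) and qq[: len(pp)] == pp


class MBBRegistry:
    """The MBB list: reference-anchored identifier table.

    Maintains the invariants (over registered entries ``a``, ``b``):
    equal reaction sets share one identifier, and for laminar (nested)
    families a strict containment ``react(a) < react(b)`` makes ``id(b)``
    a dotted prefix of ``id(a)``.
    """

    def __init__(self) -> None:
        self.reference_entries: list[RegistryEntry] = []
        self.by_nodes: dict[frozenset[NodeKey], RegistryEntry] = {}
        self._covered: set[NodeKey] = set()
        self._next_base = 0

    # -- construction -----------------------------------------------------

    @classmethod
    def from_reference(cls, reference_mdag: MDag) -> "MBBRegistry":
        reg = cls()
        for mbb in reference_mdag.mbbs:
            entry = RegistryEntry(
                identifier=str(reg._next_base),
                nodes=mbb.member_nodes,
                is_reference=True,
            )
            reg._next_base += 1
            reg.reference_entries.append(entry)
            reg.by_nodes[entry.nodes] = entry
            reg._covered |= mbb.member_nodes
            entry.instances.append(mbb)
            mbb.identifier = entry.identifier
        return reg

    # -- queries ----------------------------------------------------------

    def identifier_of(self, nodes: Iterable[NodeKey]) -> str | None:
        entry = self.by_nodes.get(frozenset(nodes))
        return entry.identifier if entry else None

    def entries(self) -> list[RegistryEntry]:
        return list(self.by_nodes.values())

    # -- registration -----------------------------------------------------

    def register(self, mbb: MBB) -> str:
        """Register one block and return (and set) its identifier."""
        nodes = mbb.member_nodes
        uncovered = nodes - self._covered
        if uncovered:
            raise ValidationError(
                f"MBB contains reaction nodes outside the reference: {sorted(uncovered)[:3]}"
            )

        entry = self.by_nodes.get(nodes)
        if entry is None:
            host = next(
                (r for r in self.reference_entries if nodes < r.nodes), None
            )
            if host is not None:
                entry = self._register_under(host, nodes)
            else:
                # Incomparable with every reference block (e.g. spanning
                # two of them): a fresh base identifier.
                entry = RegistryEntry(identifier=str(self._next_base), nodes=nodes)
                self._next_base += 1
                self.by_nodes[nodes] = entry

        entry.instances.append(mbb)
        mbb.identifier = entry.identifier
        return entry.identifier

    def _register_under(self, host: RegistryEntry, nodes: frozenset[NodeKey]) -> RegistryEntry:
        # Smallest registered superset within the host's subtree, the
        # host itself included; ties on size break on the smaller
        # identifier for determinism.
        candidates = [host] + [
            e for e in self._subtree(host) if nodes < e.nodes
        ]
        parent = min(
            candidates,
            key=lambda e: (len(e.nodes), tuple(int(c) for c in e.identifier.split("."))),
        )

        entry = RegistryEntry(
            identifier=parent.next_child_identifier(), nodes=nodes, parent=parent
        )
        parent.children.append(entry)
        self.by_nodes[nodes] = entry

        # Entries previously registered beside the new one but strictly
        # inside it move underneath it, and their subset trees are
        # re-prefixed; already-labeled m-DAGs pick the change up through
        # the entry instances.
        for sibling in [c for c in parent.children if c is not entry]:
            if sibling.nodes < nodes:
                parent.children.remove(sibling)
                sibling.parent = entry
                entry.children.append(sibling)
                self._rename(sibling, entry.next_child_identifier())
        return entry

    def _subtree(self, entry: RegistryEntry) -> list[RegistryEntry]:
        out: list[RegistryEntry] = []
        stack = list(entry.children)
        while stack:
            e = stack.pop()
            out.append(e)
            stack.extend(e.children)
        return out

    def _rename(self, entry: RegistryEntry, new_identifier: str) -> None:
        entry.identifier = new_identifier
        for inst in entry.instances:
            inst.identifier = new_identifier
        for child in entry.children:
            suffix = child.identifier.rsplit(".", 1)[-1]
            self._rename(child, f"{new_identifier}.{suffix}")

    # -- serialization ----------------------------------------------------

    def to_json(self, path) -> None:
        order = sorted(self.by_nodes.values(), key=lambda e: e.identifier.split("."))
        payload = {
            "next_base": self._next_base,
            "entries": [
                {
                    "identifier": e.identifier,
                    "nodes": [list(k) for k in sorted(e.nodes)],
                    "parent": e.parent.identifier if e.parent else None,
                    "next_child": e._next_child,
                    "is_reference": e.is_reference,
                }
                for e in order
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=1) + "\n")

    @classmethod
    def from_json(cls, path) -> "MBBRegistry":
        payload = json.loads(Path(path).read_text())
        reg = cls()
        reg._next_base = payload["next_base"]
        by_id: dict[str, RegistryEntry] = {}
        for spec in payload["entries"]:
            entry = RegistryEntry(
                identifier=spec["identifier"],
                nodes=frozenset(tuple(k) for k in spec["nodes"]),
                is_reference=spec["is_reference"],
            )
            entry._next_child = spec["next_child"]
            by_id[entry.identifier] = entry
            reg.by_nodes[entry.nodes] = entry
            if entry.is_reference:
                reg.reference_entries.append(entry)
                reg._covered |= entry.nodes
        for spec in payload["entries"]:
            if spec["parent"] is not None:
                child = by_id[spec["identifier"]]
                parent = by_id[spec["parent"]]
                child.parent = parent
                parent.children.append(child)
        return reg


def init_registry(reference_mdag: MDag) -> MBBRegistry:
    """Seed a registry from the reference m-DAG's blocks (base identifiers)."""
    return MBBRegistry.from_reference(reference_mdag)


def assign_identifier(mbb: MBB, registry: MBBRegistry) -> str:
    """Register one MBB and return its identifier (registry updated)."""
    return registry.register(mbb)


def relabel_mdag(mdag: MDag, registry: MBBRegistry) -> MDag:
    """Assign identifiers to every block of an m-DAG, in place.

    Returns the same m-DAG for convenience.  Blocks already equal to a
    registered entry reuse its identifier; new blocks are registered,
    which may re-prefix earlier entries (and earlier m-DAGs) when a new
    block strictly contains them.
    """
    for mbb in mdag.mbbs:
        registry.register(mbb)
    return mdag
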