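"""Readers and writers for pathway data and analysis results.

Two input formats carry pathway reaction sets:

* the canonical **reaction table** — a 5-column TSV (or a JSON array of
  objects with the same keys): ``reaction_id``, ``ec_numbers``,
  ``substrates``, ``products``, ``reversible``.  Multi-valued cells are
  semicolon-separated.  This format is what the synthetic generator
  emits and what the command line consumes.
* **KGML**, the KEGG Markup Language, read through Biopython's
  ``Bio.KEGG.KGML`` parser.  EC annotations are taken from enzyme
  entries linked to each reaction; reactions without one get the
  unknown-enzyme placeholder.

Output formats: m-DAGs as GraphML, Graphviz DOT or a JSON dialect that
round-trips exactly; compound-similarity matrices and distance matrices
as CSV; dendrograms as Newick (see :mod:`metadag.clustering`).
"""

from __future__ import annotations

import csv
import io
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Mapping, Sequence

import pandas as pd
from Bio.KEGG.KGML import KGML_parser

from .errors import FormatError, ValidationError
from .reaction_graph import UNKNOWN_EC, ECNumber

if TYPE_CHECKING:  # pragma: no cover
    from .mdag import MDag

logger = logging.getLogger(__name__)

__all__ = [
    "Reaction",
    "CompoundSimilarityTable",
    "read_reaction_table",
    "write_reaction_table",
    "read_kgml",
    "read_compound_matrix",
    "write_mdag",
    "read_mdag_json",
]

_COLUMNS = ("reaction_id", "ec_numbers", "substrates", "products", "reversible")


@dataclass(frozen=True)
class Reaction:
    """One chemical reaction record: R = (substrates, enzymes, products).

    ``ec_numbers`` may list several enzymes; the reaction graph then gets
    one node per enzyme.  ``reversible`` reactions are later expanded to
    forward and backward nodes.
    """

    reaction_id: str
    ec_numbers: tuple[str, ...]
    substrates: frozenset[str]
    products: frozenset[str]
    reversible: bool

    def __post_init__(self) -> None:
        if not self.reaction_id:
            raise ValidationError("empty reaction_id")
        if not self.substrates or not self.products:
            raise ValidationError(
                f"reaction {self.reaction_id}: substrates and products must be non-empty"
            )
        if not self.ec_numbers:
            raise ValidationError(f"reaction {self.reaction_id}: no EC numbers")
        for ec in self.ec_numbers:
            ECNumber.parse(ec)  # raises on malformed codes


def _make_reaction(
    reaction_id: str,
    ec_numbers: Sequence[str] | str,
    substrates: Sequence[str] | str,
    products: Sequence[str] | str,
    reversible,
) -> Reaction:
    def split(value, what: str) -> tuple[str, ...]:
        if isinstance(value, str):
            parts = [t.strip() for t in value.split(";")]
        else:
            parts = [str(t).strip() for t in value]
        parts = [p for p in parts if p]
        if not parts:
            raise ValidationError(f"reaction {reaction_id!r}: empty {what}")
        return tuple(parts)

    if isinstance(reversible, str):
        flag = reversible.strip().lower()
        if flag in ("true", "1", "yes", "reversible"):
            reversible = True
        elif flag in ("false", "0", "no", "irreversible"):
            reversible = False
        else:
            raise FormatError(f"reaction {reaction_id!r}: bad reversible flag {flag!r}")

    ecs = split(ec_numbers, "ec_numbers")
    # Deduplicate enzymes while preserving order: a repeated EC would
    # collide on the (reaction, direction, enzyme) node key.
    ecs = tuple(dict.fromkeys(ecs))
    return Reaction(
        reaction_id=str(reaction_id).strip(),
        ec_numbers=ecs,
        substrates=frozenset(split(substrates, "substrates")),
        products=frozenset(split(products, "products")),
        reversible=bool(reversible),
    )


def _check_unique(records: list[Reaction]) -> list[Reaction]:
    seen: set[str] = set()
    for rec in records:
        if rec.reaction_id in seen:
            raise ValidationError(f"duplicate reaction_id {rec.reaction_id!r}")
        seen.add(rec.reaction_id)
    return records


def read_reaction_table(path, dialect: str | None = None) -> list[Reaction]:
    """Read a pathway reaction table from TSV or JSON.

    ``dialect`` is ``"tsv"`` or ``"json"``; when omitted it is inferred
    from the file extension.
    """
    path = Path(path)
    if dialect is None:
        dialect = "json" if path.suffix.lower() == ".json" else "tsv"
    if dialect == "json":
        try:
            raw = json.loads(path.read_text())
        except json.JSONDecodeError as exc:
            raise FormatError(f"{path}: not valid JSON: {exc}") from exc
        if not isinstance(raw, list):
            raise FormatError(f"{path}: expected a JSON array of reaction objects")
        records = []
        for obj in raw:
            missing = [c for c in _COLUMNS if c not in obj]
            if missing:
                raise FormatError(f"{path}: missing key(s) {missing} in {obj!r}")
            records.append(_make_reaction(*(obj[c] for c in _COLUMNS)))
        return _check_unique(records)
    if dialect == "tsv":
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh, delimiter="\t")
            header = reader.fieldnames or []
            header = [h.strip() for h in header]
            missing = [c for c in _COLUMNS if c not in header]
            if missing:
                raise FormatError(f"{path}: missing column(s) {missing}")
            records = []
            for row in reader:
                row = {k.strip(): (v or "") for k, v in row.items() if k}
                records.append(_make_reaction(*(row[c] for c in _COLUMNS)))
        return _check_unique(records)
    raise ValueError(f"unknown dialect {dialect!r}")


def write_reaction_table(records: Iterable[Reaction], path, dialect: str | None = None) -> None:
    """Write reactions in the canonical table format (TSV or JSON)."""
    path = Path(path)
    if dialect is None:
        dialect = "json" if path.suffix.lower() == ".json" else "tsv"
    rows = [
        {
            "reaction_id": r.reaction_id,
            "ec_numbers": ";".join(r.ec_numbers),
            "substrates": ";".join(sorted(r.substrates)),
            "products": ";".join(sorted(r.products)),
            "reversible": str(r.reversible).lower(),
        }
        for r in sorted(records, key=lambda r: r.reaction_id)
    ]
    if dialect == "json":
        path.write_text(json.dumps(rows, indent=1) + "\n")
    else:
        with open(path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=_COLUMNS, delimiter="\t")
            writer.writeheader()
            writer.writerows(rows)


def _strip_prefix(name: str) -> str:
    return name.split(":", 1)[1] if ":" in name else name


def read_kgml(path) -> list[Reaction]:
    """Read reaction records from a KGML pathway file.

    ``rn:``/``cpd:`` prefixes are stripped; a reaction's EC numbers come
    from the enzyme entries that reference it, falling back to the
    unknown-enzyme placeholder.  Reactions lacking substrates or products
    are skipped with a warning, since KGML dialects vary in completeness.
    """
    path = Path(path)
    try:
        pathway = KGML_parser.read(path.read_text())
    except Exception as exc:  # XML/KGML structure errors
        raise FormatError(f"{path}: cannot parse KGML: {exc}") from exc

    # Map reaction name -> EC codes, from enzyme entries.
    ecs_by_reaction: dict[str, list[str]] = {}
    for entry in pathway.entries.values():
        if entry.type != "enzyme" or not entry.reaction:
            continue
        codes = [
            _strip_prefix(tok)
            for tok in entry.name.split()
            if tok.startswith("ec:")
        ]
        for rname in entry.reaction.split():
            ecs_by_reaction.setdefault(rname, []).extend(codes)

    records: dict[str, Reaction] = {}
    for reaction in pathway.reactions:
        names = reaction.name.split()
        try:
            subs = [_strip_prefix(s.name) for s in reaction.substrates]
            prods = [_strip_prefix(p.name) for p in reaction.products]
        except KeyError:
            logger.warning("%s: reaction %s references unknown compounds; skipped",
                           path, reaction.name)
            continue
        if not subs or not prods:
            logger.warning("%s: reaction %s lacks substrates or products; skipped",
                           path, reaction.name)
            continue
        reversible = reaction.type == "reversible"
        for name in names:
            rid = _strip_prefix(name)
            ecs = ecs_by_reaction.get(name) or [UNKNOWN_EC]
            rec = _make_reaction(rid, ecs, subs, prods, reversible)
            if rid in records:
                prev = records[rid]
                rec = _make_reaction(
                    rid,
                    tuple(dict.fromkeys(prev.ec_numbers + rec.ec_numbers)),
                    prev.substrates | rec.substrates,
                    prev.products | rec.products,
                    prev.reversible or rec.reversible,
                )
            records[rid] = rec
    return [records[k] for k in sorted(records)]


class CompoundSimilarityTable:
    """Symmetric compound-compound similarity scores in [0, 1].

    Keys are unordered compound pairs.  A lookup of an absent pair
    returns ``default`` (0 unless configured otherwise); self-similarity
    is always 1.  The table plugs into the similarity stack in place of
    an external chemical-structure similarity tool.
    """

    def __init__(self, entries: Mapping[frozenset, float] | None = None,
                 default: float = 0.0):
        self._entries: dict[frozenset, float] = dict(entries or {})
        for pair, score in self._entries.items():
            if not 0.0 <= score <= 1.0:
                raise ValidationError(f"score {score} for {sorted(pair)} outside [0, 1]")
        if not 0.0 <= default <= 1.0:
            raise ValidationError(f"default score {default} outside [0, 1]")
        self.default = default

    def __call__(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        return self._entries.get(frozenset((a, b)), self.default)

    def __len__(self) -> int:
        return len(self._entries)


def read_compound_matrix(path, default: float = 0.0) -> CompoundSimilarityTable:
    """Read a compound-similarity CSV with columns compound_a, compound_b, score."""
    df = pd.read_csv(path)
    needed = {"compound_a", "compound_b", "score"}
    if not needed.issubset(df.columns):
        raise FormatError(f"{path}: expected columns {sorted(needed)}, got {list(df.columns)}")
    entries: dict[frozenset, float] = {}
    for row in df.itertuples(index=False):
        score = float(row.score)
        if not 0.0 <= score <= 1.0:
            raise ValidationError(
                f"{path}: score {score} for ({row.compound_a}, {row.compound_b}) outside [0, 1]"
            )
        entries[frozenset((str(row.compound_a).strip(), str(row.compound_b).strip()))] = score
    return CompoundSimilarityTable(entries, default=default)


# ---------------------------------------------------------------------------
# m-DAG writers


def _mdag_to_networkx(mdag: "MDag"):
    import networkx as nx

    g = nx.DiGraph()
    order = mdag.sorted_mbbs()
    index = {id(m): i for i, m in enumerate(order)}
    for i, mbb in enumerate(order):
        g.add_node(
            i,
            identifier=mbb.identifier or "",
            n_nodes=len(mbb.member_nodes),
            n_reactions=len(mbb.reaction_ids),
            singleton=mbb.is_singleton,
        )
    for a, b in mdag.arcs:
        g.add_edge(index[id(a)], index[id(b)])
    return g, order


def write_mdag(mdag: "MDag", path, format: str | None = None) -> None:
    """Write an m-DAG as GraphML, DOT or JSON.

    Nodes carry their hierarchical identifier, reaction count, and a
    singleton flag (single-reaction blocks, the natural candidates for
    essential reactions).  The JSON form round-trips exactly through
    :func:`read_mdag_json`.
    """
    import networkx as nx

    path = Path(path)
    if format is None:
        format = {".graphml": "graphml", ".dot": "dot", ".gv": "dot"}.get(
            path.suffix.lower(), "json"
        )
    if format == "graphml":
        g, _ = _mdag_to_networkx(mdag)
        nx.write_graphml(g, path)
        return
    if format == "dot":
        g, order = _mdag_to_networkx(mdag)
        lines = ["digraph mdag {"]
        for i in g.nodes:
            d = g.nodes[i]
            label = d["identifier"] or f"mbb{i}"
            fill = "yellow" if d["singleton"] else "grey"
            lines.append(
                f'  n{i} [label="{label} ({d["n_reactions"]})", style=filled, fillcolor={fill}];'
            )
        for a, b in g.edges:
            lines.append(f"  n{a} -> n{b};")
        lines.append("}")
        path.write_text("\n".join(lines) + "\n")
        return
    if format == "json":
        order = mdag.sorted_mbbs()
        index = {id(m): i for i, m in enumerate(order)}
        payload = {
            "source_organism": mdag.source_organism,
            "mbbs": [
                {
                    "identifier": m.identifier,
                    "nodes": [list(k) for k in sorted(m.member_nodes)],
                }
                for m in order
            ],
            "arcs": sorted([index[id(a)], index[id(b)]] for a, b in mdag.arcs),
        }
        path.write_text(json.dumps(payload, indent=1) + "\n")
        return
    raise ValueError(f"unknown m-DAG format {format!r}")


def read_mdag_json(path) -> "MDag":
    """Read an m-DAG previously written by :func:`write_mdag` (json format)."""
    from .mdag import MBB, MDag

    payload = json.loads(Path(path).read_text())
    mbbs = [
        MBB(
            member_nodes=frozenset(tuple(k) for k in spec["nodes"]),
            identifier=spec.get("identifier"),
        )
        for spec in payload["mbbs"]
    ]
    arcs = {(mbbs[i], mbbs[j]) for i, j in payload["arcs"]}
    return MDag(mbbs=mbbs, arcs=arcs, source_organism=payload.get("source_organism", ""))


def write_distance_csv(labels: Sequence[str], matrix, path) -> None:
    """Write a square labeled distance matrix as CSV."""
    df = pd.DataFrame(matrix, index=list(labels), columns=list(labels))
    df.to_csv(path, index_label="")


def read_distance_csv(path):
    """Read a square labeled distance matrix CSV -> (labels, ndarray)."""
    df = pd.read_csv(path, index_col=0)
    if list(df.index) != list(df.columns):
        raise FormatError(f"{path}: row and column labels differ")
    return list(df.index), df.to_numpy(dtype=float)
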