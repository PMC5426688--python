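"""Synthetic pathway generator with known ground-truth block structure.

Real reference pathways look like a few large strongly connected blocks
joined by single-reaction connectors.  The generator reproduces exactly
that shape analytically:

* each intended block is a directed compound cycle — reaction ``i``
  consumes compound ``i`` and produces compound ``i + 1`` (mod the block
  size) — which is a strongly connected component by construction;
* linker reactions are irreversible single-reaction bridges between
  consecutive blocks, so they are guaranteed singleton MBBs and cut
  nodes (the pathway's essential reactions);
* compound tokens are namespaced per block, so no accidental cross-block
  arcs arise.

Organism pathways are derived as random subsets of the reference, which
guarantees the containment property real KEGG pathways exhibit: every
organism MBB nests inside exactly one reference MBB.

The generator makes no attempt to mimic real reaction chemistry or
realistic EC-number frequencies; it exists to give every analysis stage
a certified ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ValidationError
from .io_formats import Reaction
from .reaction_graph import NodeKey, expand_reaction

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "OrganismPathway",
    "generate_reference",
    "derive_organism",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a synthetic reference pathway.

    ``block_sizes`` gives the number of reactions in each intended
    strongly connected block (its length is the block count);
    ``n_linkers`` single-reaction irreversible connectors are spread
    round-robin over the gaps between consecutive blocks.
    ``reversible_fraction`` of block reactions are flagged reversible
    (which cannot change block membership: a backward node always forms
    a 2-cycle with its forward partner), and ``multi_ec_fraction`` get a
    second catalyzing enzyme.
    """

    block_sizes: tuple[int, ...] = (4, 4, 3)
    n_linkers: int = 2
    reversible_fraction: float = 0.5
    multi_ec_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.block_sizes:
            raise ValidationError("need at least one block")
        if any(s < 1 for s in self.block_sizes):
            raise ValidationError("block sizes must be >= 1")
        if self.n_linkers < 0:
            raise ValidationError("n_linkers must be >= 0")
        for f in (self.reversible_fraction, self.multi_ec_fraction):
            if not 0.0 <= f <= 1.0:
                raise ValidationError(f"fraction {f} outside [0, 1]")


@dataclass
class GroundTruth:
    """What the generator promises about its output.

    ``partition`` lists, per intended MBB, the exact set of reaction-graph
    node keys (blocks first, then linker singletons); ``essential_linkers``
    are the linker reaction ids, each a guaranteed singleton cut node of
    the m-DAG whenever it joins two non-empty neighbours.
    """

    partition: list[frozenset[NodeKey]]
    block_reaction_ids: list[frozenset[str]]
    essential_linkers: list[str]


def _block_reaction(block: int, i: int, size: int, reversible: bool,
                    extra_ec: bool) -> Reaction:
    ecs = [f"{block + 1}.{i + 1}.1.1"]
    if extra_ec:
        ecs.append(f"{block + 1}.{i + 1}.2.1")
    return Reaction(
        reaction_id=f"B{block}R{i:02d}",
        ec_numbers=tuple(ecs),
        substrates=frozenset({f"C{block}_{i}"}),
        products=frozenset({f"C{block}_{(i + 1) % size}"}),
        reversible=reversible,
    )


def generate_reference(spec: SyntheticSpec) -> tuple[list[Reaction], GroundTruth]:
    """Generate the reference pathway and its certified block structure."""
    rng = np.random.default_rng(spec.seed)
    records: list[Reaction] = []
    blocks: list[list[Reaction]] = []

    for b, size in enumerate(spec.block_sizes):
        block_records = []
        for i in range(size):
            reversible = size > 1 and rng.random() < spec.reversible_fraction
            extra_ec = rng.random() < spec.multi_ec_fraction
            block_records.append(_block_reaction(b, i, size, reversible, extra_ec))
        blocks.append(block_records)
        records.extend(block_records)

    # Linkers: gap g joins block g to block g+1 through a private chain
    # of compounds; extra linkers extend gap chains round-robin.
    n_gaps = max(len(spec.block_sizes) - 1, 1)
    per_gap: list[int] = [0] * n_gaps
    for j in range(spec.n_linkers):
        per_gap[j % n_gaps] += 1
    linkers: list[Reaction] = []
    for g, count in enumerate(per_gap):
        if count == 0 or len(spec.block_sizes) < 2:
            continue
        src_block, dst_block = g, g + 1
        # chain: block g's compound 0 -> L0 -> ... -> block g+1's compound 0
        stops = [f"C{src_block}_0"] + [f"L{g}_{k}" for k in range(count - 1)] + [
            f"C{dst_block}_0"
        ]
        for k in range(count):
            linkers.append(
                Reaction(
                    reaction_id=f"LINK{g}_{k}",
                    ec_numbers=(f"9.{g + 1}.{k + 1}.1",),
                    substrates=frozenset({stops[k]}),
                    products=frozenset({stops[k + 1]}),
                    reversible=False,
                )
            )
    records.extend(linkers)

    partition = [
        frozenset(n.key for rec in block_records for n in expand_reaction(rec))
        for block_records in blocks
    ]
    partition += [
        frozenset(n.key for n in expand_reaction(rec)) for rec in linkers
    ]
    truth = GroundTruth(
        partition=partition,
        block_reaction_ids=[
            frozenset(rec.reaction_id for rec in block_records)
            for block_records in blocks
        ],
        essential_linkers=[rec.reaction_id for rec in linkers],
    )
    return records, truth


@dataclass
class OrganismPathway:
    """A derived organism pathway: a record subset carrying its group tag."""

    organism_id: str
    group: str
    records: list[Reaction]


def derive_organism(
    records: Sequence[Reaction],
    drop_fraction: float,
    group: str = "",
    seed: int = 0,
    organism_id: str | None = None,
    protect_linkers: bool = True,
) -> OrganismPathway:
    """Derive an organism pathway as a random subset of the reference.

    ``drop_fraction`` of the eligible reactions are removed (linker
    reactions are protected by default, keeping the organism's m-DAG
    connected).  The result is a strict record subset, so every organism
    MBB provably nests inside a reference MBB.
    """
    if not 0.0 <= drop_fraction < 1.0:
        raise ValidationError(f"drop_fraction {drop_fraction} outside [0, 1)")
    rng = np.random.default_rng(seed)
    eligible = [
        r for r in records
        if not (protect_linkers and r.reaction_id.startswith("LINK"))
    ]
    n_drop = int(round(drop_fraction * len(eligible)))
    drop_ids = set(
        rng.choice([r.reaction_id for r in eligible], size=n_drop, replace=False)
    ) if n_drop else set()
    kept = [r for r in records if r.reaction_id not in drop_ids]
    if not kept:
        kept = list(records[:1])
    if organism_id is None:
        organism_id = f"org{seed}" + (f"_{group}" if group else "")
    return OrganismPathway(organism_id=organism_id, group=group, records=kept)
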