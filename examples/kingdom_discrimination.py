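"""Group reference m-DAGs and group-discriminating blocks and reactions.

Two synthetic groups are built so each lacks a different reference
block.  The per-group reference m-DAG (union of the group's pathways,
then condensation) and the occurrence tables then expose which building
blocks and which reactions are diagnostic of a group: observing such a
reaction pins down the organism's group.
"""

from metadag import (
    SyntheticSpec,
    build_mdag,
    build_reaction_graph,
    build_reference_graph,
    discriminating_mbbs,
    discriminating_reactions,
    generate_reference,
    init_registry,
    kingdom_reference,
    occurrence_table,
    relabel_mdag,
)

spec = SyntheticSpec(block_sizes=(3, 3, 3), n_linkers=2,
                     reversible_fraction=0.0, multi_ec_fraction=0.0, seed=3)
records, truth = generate_reference(spec)

graphs = []
for group, dropped_block in (("G1", truth.block_reaction_ids[0]),
                             ("G2", truth.block_reaction_ids[2])):
    subset = [r for r in records if r.reaction_id not in dropped_block]
    graphs.append(
        build_reaction_graph(subset, organism_id=f"org_{group}", group=group)
    )

registry = init_registry(build_mdag(build_reference_graph(graphs)))
mbb_ids, reaction_ids = {}, {}
for group in ("G1", "G2"):
    gref = relabel_mdag(kingdom_reference(graphs, group), registry)
    mbb_ids[group] = {m.identifier for m in gref.mbbs}
    reaction_ids[group] = {
        rid for g in graphs if g.group == group for rid in g.reaction_ids()
    }
    print(f"{group} reference m-DAG: {len(gref.mbbs)} blocks "
          f"{sorted(mbb_ids[group])}")

print("\nblocks absent from at least one group:")
print(discriminating_mbbs(occurrence_table(mbb_ids)))
print("\nreactions present in exactly one group (group-diagnostic):")
print(discriminating_reactions(occurrence_table(reaction_ids)))
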