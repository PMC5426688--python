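"""Condense a small pyruvate-centered pathway into its metabolic DAG.

Builds a hand-sized pathway around pyruvate kinase (R00200) and lactate
dehydrogenase (R00703, reversible), computes the reaction graph, its
strongly connected components (the metabolic building blocks) and the
condensation, and prints the blocks, the essential reactions and the
pivot classes around R00200.
"""

from metadag import (
    Reaction,
    build_mdag,
    build_reaction_graph,
    classify_mbbs,
    topology_report,
)


def reaction(rid, ec, subs, prods, reversible=False):
    return Reaction(rid, (ec,), frozenset(subs), frozenset(prods), reversible)


# A toy upper-glycolysis cycle feeding phosphoenolpyruvate, the
# irreversible pyruvate-kinase step, and reversible downstream chemistry.
records = [
    reaction("R_up1", "5.3.1.9", {"G6P"}, {"F6P"}, reversible=True),
    reaction("R_up2", "2.7.1.11", {"F6P"}, {"FBP"}),
    reaction("R_up3", "3.1.3.11", {"FBP"}, {"F6P", "PEP"}),
    reaction("R00200", "2.7.1.40", {"PEP"}, {"PYR"}),  # pyruvate kinase
    reaction("R00703", "1.1.1.27", {"PYR"}, {"LAC"}, reversible=True),
]

graph = build_reaction_graph(records, organism_id="toy")
mdag = build_mdag(graph)
report = topology_report(mdag)
classes = classify_mbbs(mdag, "R00200")

print(f"reaction graph: {len(graph.nodes)} nodes, {len(graph.arcs)} arcs")
print(f"m-DAG: {len(mdag.mbbs)} building blocks, {len(mdag.arcs)} arcs\n")
for mbb in mdag.sorted_mbbs():
    kind = "singleton" if mbb.is_singleton else f"{mbb.n_nodes}-node block"
    print(f"  MBB {sorted(mbb.reaction_ids)}  ({kind}, class={classes.class_of[mbb]})")

essential = sorted(next(iter(m.reaction_ids)) for m in report.essential_reactions)
print(f"\nessential reactions (singleton cut nodes): {essential}")
print("removing any of them disconnects the pathway's m-DAG.")
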