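import numpy as np
import pytest

from metadag import Reaction, ReactionGraph
from metadag.reaction_graph import ECNumber, ReactionNode, FORWARD


def make_reaction(rid, substrates, products, ec="1.1.1.1", reversible=False):
    ecs = (ec,) if isinstance(ec, str) else tuple(ec)
    return Reaction(
        reaction_id=rid,
        ec_numbers=ecs,
        substrates=frozenset(substrates),
        products=frozenset(products),
        reversible=reversible,
    )


def graph_from_edges(n, edges, organism_id=""):
    """A ReactionGraph with ``n`` abstract nodes and the given arc set.

    Bypasses the metabolite arc rule so SCC/condensation/topology
    machinery can be exercised on arbitrary digraphs.
    """
    nodes = {}
    for i in range(n):
        node = ReactionNode(
            reaction_id=f"R{i:03d}",
            direction=FORWARD,
            enzyme=ECNumber.parse("1.1.1.1"),
            inputs=frozenset({f"in{i}"}),
            outputs=frozenset({f"out{i}"}),
        )
        nodes[node.key] = node
    keys = sorted(nodes)
    arcs = {(keys[a], keys[b]) for a, b in edges if a != b}
    return ReactionGraph(organism_id=organism_id, nodes=nodes, arcs=arcs)


def random_digraph(rng, n_max=50, p=None):
    n = int(rng.integers(2, n_max + 1))
    if p is None:
        p = float(rng.uniform(0.02, 3.0 / n))
    edges = [(i, j) for i in range(n) for j in range(n)
             if i != j and rng.random() < p]
    return graph_from_edges(n, edges)


# The largest building block of the human glycolysis pathway, used as a
# worked counting example: 21 reactions, two of them catalyzed by two
# enzymes.  Compounds are wired in a single cycle so the reactions form
# one strongly connected block by construction.
GLYCOLYSIS_BIG_BLOCK = [
    # (reaction_id, reversible, n_enzymes)
    ("R00658", True, 1), ("R00959", True, 1), ("R01015", True, 1),
    ("R01061", True, 1), ("R01070", True, 1), ("R01512", True, 1),
    ("R01516", True, 1), ("R01518", True, 1), ("R01600", False, 2),
    ("R01602", True, 1), ("R01662", True, 1), ("R01786", False, 2),
    ("R01788", False, 1), ("R02739", True, 1), ("R02740", True, 1),
    ("R03321", True, 1), ("R04779", False, 1), ("R04780", False, 1),
    ("R09085", False, 1), ("R09086", True, 1), ("R09532", False, 1),
]


def glycolysis_block_records():
    n = len(GLYCOLYSIS_BIG_BLOCK)
    records = []
    for i, (rid, reversible, n_enzymes) in enumerate(GLYCOLYSIS_BIG_BLOCK):
        ecs = [f"{k + 2}.{i + 1}.1.1" for k in range(n_enzymes)]
        records.append(
            make_reaction(
                rid,
                substrates={f"C{i:02d}"},
                products={f"C{(i + 1) % n:02d}"},
                ec=ecs,
                reversible=reversible,
            )
        )
    return records


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
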