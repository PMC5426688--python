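import networkx as nx
import numpy as np
import pytest

from metadag import (
    build_mdag,
    build_reaction_graph,
    build_reference_graph,
    classify_mbbs,
    condense,
    discriminating_mbbs,
    discriminating_reactions,
    kingdom_reference,
    occurrence_table,
    strongly_connected_components,
    topology_report,
)
from metadag.errors import ValidationError
from metadag.mdag import FROM_PIVOT, OTHER, PIVOT, TO_PIVOT, MBB

from conftest import (
    glycolysis_block_records,
    graph_from_edges,
    make_reaction,
    random_digraph,
)


def reachability_partition(graph):
    """Brute-force oracle: mutual-reachability equivalence classes."""
    g = graph.to_networkx()
    keys = list(graph.node_keys)
    parts = []
    assigned = set()
    for u in keys:
        if u in assigned:
            continue
        part = {
            v
            for v in keys
            if v == u or (nx.has_path(g, u, v) and nx.has_path(g, v, u))
        }
        parts.append(frozenset(part))
        assigned |= part
    return set(parts)


class TestSCC:
    def test_reversible_reaction_is_one_two_node_block(self):
        g = build_reaction_graph(
            [make_reaction("R00703", {"C00022"}, {"C00186"}, ec="1.1.1.27", reversible=True)]
        )
        (mbb,) = strongly_connected_components(g)
        assert mbb.n_nodes == 2
        assert mbb.reaction_ids == {"R00703"}

    def test_acyclic_chain_gives_singletons(self):
        g = graph_from_edges(5, [(i, i + 1) for i in range(4)])
        parts = strongly_connected_components(g)
        assert len(parts) == 5
        assert all(m.is_singleton for m in parts)

    def test_matches_reachability_oracle_on_random_digraphs(self, rng):
        for _ in range(30):
            g = random_digraph(rng, n_max=40)
            mine = {m.member_nodes for m in strongly_connected_components(g)}
            assert mine == reachability_partition(g)

    def test_matches_networkx_scc(self, rng):
        for _ in range(10):
            g = random_digraph(rng, n_max=40)
            mine = {m.member_nodes for m in strongly_connected_components(g)}
            ref = {frozenset(c) for c in nx.strongly_connected_components(g.to_networkx())}
            assert mine == ref

    def test_partition_property(self, rng):
        g = random_digraph(rng, n_max=30)
        parts = strongly_connected_components(g)
        assert sum(m.n_nodes for m in parts) == len(g.nodes)
        assert len({k for m in parts for k in m.member_nodes}) == len(g.nodes)

    def test_deterministic_component_order(self, rng):
        g = random_digraph(rng, n_max=30)
        a = [m.member_nodes for m in strongly_connected_components(g)]
        b = [m.member_nodes for m in strongly_connected_components(g)]
        assert a == b


class TestCondense:
    def test_two_cycle_condenses_to_point(self):
        g = graph_from_edges(2, [(0, 1), (1, 0)])
        mdag = build_mdag(g)
        assert len(mdag.mbbs) == 1 and not mdag.arcs

    def test_chain_stays_path(self):
        g = graph_from_edges(3, [(0, 1), (1, 2)])
        mdag = build_mdag(g)
        assert len(mdag.mbbs) == 3 and len(mdag.arcs) == 2

    def test_wrong_partition_rejected(self):
        g = graph_from_edges(3, [(0, 1)])
        keys = g.node_keys
        with pytest.raises(ValidationError):
            condense(g, [MBB(member_nodes=frozenset(keys[:2]))])

    def test_acyclicity_and_arc_faithfulness_oracle(self, rng):
        for _ in range(25):
            g = random_digraph(rng, n_max=30)
            parts = strongly_connected_components(g)
            mdag = condense(g, parts)
            assert nx.is_directed_acyclic_graph(mdag.to_networkx())
            owner = {k: m for m in parts for k in m.member_nodes}
            expected = {
                (owner[u], owner[v]) for u, v in g.arcs if owner[u] is not owner[v]
            }
            assert mdag.arcs == expected

    def test_matches_networkx_condensation(self, rng):
        g = random_digraph(rng, n_max=30)
        mdag = build_mdag(g)
        ref = nx.condensation(g.to_networkx())
        mine_arcs = {
            (frozenset(a.member_nodes), frozenset(b.member_nodes)) for a, b in mdag.arcs
        }
        ref_arcs = {
            (frozenset(ref.nodes[a]["members"]), frozenset(ref.nodes[b]["members"]))
            for a, b in ref.edges
        }
        assert mine_arcs == ref_arcs


class TestCountingConventions:
    def test_largest_glycolysis_block_counts(self):
        g = build_reaction_graph(glycolysis_block_records())
        (mbb,) = strongly_connected_components(g)
        # one unit per (reaction, enzyme) pair: 19 + 2*2 = 23
        assert mbb.n_reaction_enzyme_pairs == 23
        assert len(mbb.reaction_ids) == 21
        # graph nodes additionally split reversible reactions in two
        assert mbb.n_nodes == sum(
            (2 if rev else 1) * n_ec
            for _, rev, n_ec in __import__("conftest").GLYCOLYSIS_BIG_BLOCK
        )


class TestTopology:
    def test_middle_of_path_is_essential(self):
        mdag = build_mdag(graph_from_edges(3, [(0, 1), (1, 2)]))
        report = topology_report(mdag)
        middle = next(m for m in mdag.mbbs if m.sort_key[0] == "R001")
        assert report.essential_reactions == {middle}
        assert report.cut_nodes == {middle}
        assert len(report.bridges) == 2
        assert report.linear_paths and len(report.linear_paths[0]) == 3

    def test_single_node_is_isolated_not_cut(self):
        mdag = build_mdag(graph_from_edges(1, []))
        report = topology_report(mdag)
        assert not report.cut_nodes
        assert report.isolated == set(mdag.mbbs)

    def test_multi_reaction_cut_block_not_essential(self):
        # 2-cycle block in the middle of a path: cut node but not singleton
        g = graph_from_edges(4, [(0, 1), (1, 2), (2, 1), (2, 3)])
        mdag = build_mdag(g)
        report = topology_report(mdag)
        block = next(m for m in mdag.mbbs if m.n_nodes == 2)
        assert block in report.cut_nodes
        assert block not in report.essential_reactions

    def test_against_exhaustive_removal_oracle(self, rng):
        for _ in range(25):
            g = random_digraph(rng, n_max=30)
            mdag = build_mdag(g)
            report = topology_report(mdag)
            und = mdag.to_networkx().to_undirected()
            base = nx.number_connected_components(und)

            for m in mdag.mbbs:
                h = und.copy()
                h.remove_node(m)
                increases = (
                    h.number_of_nodes() > 0
                    and nx.number_connected_components(h) > base - (und.degree(m) == 0)
                )
                assert (m in report.cut_nodes) == bool(
                    und.degree(m) > 0 and increases
                ), "cut-node mismatch"
            for a, b in mdag.arcs:
                h = und.copy()
                h.remove_edge(a, b)
                assert ((a, b) in report.bridges) == (
                    nx.number_connected_components(h) > base
                )


class TestReference:
    def test_union_of_identical_graphs_is_idempotent(self):
        records = [
            make_reaction("R1", {"A"}, {"B"}, reversible=True),
            make_reaction("R2", {"B"}, {"C"}),
        ]
        g = build_reaction_graph(records)
        ref = build_reference_graph([g, g, g])
        assert set(ref.nodes) == set(g.nodes)
        assert ref.arcs == g.arcs

    def test_disjoint_graphs_unite(self):
        g1 = build_reaction_graph([make_reaction("R1", {"A"}, {"B"})])
        g2 = build_reaction_graph([make_reaction("R2", {"B"}, {"C"})])
        ref = build_reference_graph([g1, g2])
        assert len(ref.nodes) == 2
        assert len(ref.arcs) == 1  # arc appears once reactions are united

    def test_conflicting_compound_sets_rejected(self):
        g1 = build_reaction_graph([make_reaction("R1", {"A"}, {"B"})])
        g2 = build_reaction_graph([make_reaction("R1", {"A", "X"}, {"B"})])
        with pytest.raises(ValidationError, match="inconsistent"):
            build_reference_graph([g1, g2])

    def test_subgraph_mbbs_nest_inside_reference_mbbs(self, rng):
        """Every MBB of a record-subset organism sits inside one reference MBB."""
        from metadag import SyntheticSpec, derive_organism, generate_reference

        records, _ = generate_reference(SyntheticSpec(seed=5))
        ref_mdag = build_mdag(build_reaction_graph(records))
        for seed in range(5):
            org = derive_organism(records, 0.3, seed=seed)
            mdag = build_mdag(build_reaction_graph(org.records))
            for m in mdag.mbbs:
                hosts = [r for r in ref_mdag.mbbs if m.member_nodes <= r.member_nodes]
                assert len(hosts) == 1


class TestClassify:
    def test_path_around_pivot(self):
        g = build_reaction_graph(
            [
                make_reaction("U", {"A"}, {"B"}),
                make_reaction("P", {"B"}, {"C"}),
                make_reaction("D", {"C"}, {"D"}),
                make_reaction("Z", {"Q"}, {"W"}),
            ]
        )
        mdag = build_mdag(g)
        classes = classify_mbbs(mdag, "P")
        by_rid = {next(iter(m.reaction_ids)): cls for m, cls in classes.class_of.items()}
        assert by_rid == {"U": TO_PIVOT, "P": PIVOT, "D": FROM_PIVOT, "Z": OTHER}

    def test_absent_pivot_warns_and_defaults(self):
        mdag = build_mdag(graph_from_edges(2, [(0, 1)]))
        with pytest.warns(UserWarning, match="R00200"):
            classes = classify_mbbs(mdag, "R00200")
        assert set(classes.class_of.values()) == {OTHER}


class TestKingdomReference:
    @pytest.fixture
    def family(self):
        base = [
            make_reaction("R1", {"A"}, {"B"}, reversible=True),
            make_reaction("R2", {"B"}, {"C"}),
            make_reaction("R3", {"C"}, {"A"}),
        ]
        g_full = build_reaction_graph(base, organism_id="full", group="G1")
        g_small = build_reaction_graph(base[:2], organism_id="small", group="G1")
        g_other = build_reaction_graph(base[1:], organism_id="other", group="G2")
        return [g_full, g_small, g_other]

    def test_single_organism_group_is_its_own_mdag(self, family):
        ref = kingdom_reference(family, "G2")
        assert ref == build_mdag(family[2])

    def test_union_strategy_on_all_equals_global_reference(self, family):
        for g in family:
            g.group = "ALL"
        ref = kingdom_reference(family, "ALL", strategy="union")
        global_ref = build_mdag(build_reference_graph(family))
        assert {m.member_nodes for m in ref.mbbs} == {
            m.member_nodes for m in global_ref.mbbs
        }

    def test_maximal_strategy_keeps_larger_nested_block(self, family):
        ref = kingdom_reference(family[:2], "G1", strategy="maximal-mbb")
        union_mdag = kingdom_reference(family[:2], "G1", strategy="union")
        # the small organism's sub-blocks are swallowed by the full cycle
        assert {m.member_nodes for m in ref.mbbs} == {
            m.member_nodes for m in union_mdag.mbbs
        }

    def test_unknown_group_rejected(self, family):
        with pytest.raises(ValidationError):
            kingdom_reference(family, "NOPE")


class TestDiscrimination:
    def test_mbb_table(self):
        occ = occurrence_table(
            {
                "Bacteria": ["MBB0", "MBB179"],
                "Archaea": ["MBB0", "MBB179"],
                "Animalia": ["MBB0"],
            }
        )
        out = discriminating_mbbs(occ)
        assert list(out.index) == ["MBB179"]
        assert out.loc["MBB179", "Bacteria"] and out.loc["MBB179", "Archaea"]
        assert not out.loc["MBB179", "Animalia"]

    def test_reaction_table_exactly_one_group(self):
        occ = occurrence_table(
            {"Bacteria": ["R05133", "R00200"], "Animalia": ["R01516", "R00200"]}
        )
        out = discriminating_reactions(occ)
        assert set(out.index) == {"R05133", "R01516"}

    def test_empty_table(self):
        import pandas as pd

        empty = pd.DataFrame()
        assert discriminating_mbbs(empty).empty
        assert discriminating_reactions(empty).empty
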