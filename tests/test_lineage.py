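"""Lineage graph queries and Class I/II/III placement."""

import networkx as nx
import pytest

from halotrace.catalog import MutationKey, StrainInfo, StrainManifest
from halotrace.lineage import PRE_REFERENCE, LineageGraph, classify_mutation
from halotrace.synthetic_data import SimConfig, make_lineage


def _graph(nodes, edges):
    g = nx.DiGraph()
    for nid, role, seq in nodes:
        g.add_node(nid, role=role, sequenced=seq, lab="")
    for u, v, t in edges:
        g.add_edge(u, v, type=t)
    return LineageGraph(g)


def _manifest_from(graph: LineageGraph) -> StrainManifest:
    strains = {}
    for n, d in graph.graph.nodes(data=True):
        preds = list(graph.graph.predecessors(n))
        strains[n] = StrainInfo(
            n, preds[0] if preds else None, d["role"], d["sequenced"]
        )
    return StrainManifest(strains)


@pytest.fixture()
def toy_tree():
    """Six-node tree: REF -> WT(seq); REF -> P(unseq) -> K1(seq), K2(seq),
    K2 -> K2b(seq double knockout)."""
    return _graph(
        [
            ("REF", "wild_type", False),
            ("WT", "wild_type", True),
            ("P", "parental", False),
            ("K1", "knockout", True),
            ("K2", "knockout", True),
            ("K2b", "knockout", True),
        ],
        [
            ("REF", "WT", "transfer"),
            ("REF", "P", "manipulation"),
            ("P", "K1", "manipulation"),
            ("P", "K2", "manipulation"),
            ("K2", "K2b", "manipulation"),
        ],
    )


KEY = MutationKey("chr", 100, "SNP", "A", "T", 1)


def test_sequenced_descendants_basic(toy_tree):
    assert toy_tree.sequenced_descendants("K1") == {"K1"}
    assert toy_tree.sequenced_descendants("P") == {"K1", "K2", "K2b"}
    assert toy_tree.sequenced_descendants("REF") == {"WT", "K1", "K2", "K2b"}
    with pytest.raises(KeyError):
        toy_tree.sequenced_descendants("nope")


def test_sequenced_descendants_matches_reachability_oracle():
    for seed in range(10):
        graph, _ = make_lineage(SimConfig(seed=seed))
        g = graph.graph
        for node in g.nodes:
            brute = {
                n
                for n in g.nodes
                if g.nodes[n]["sequenced"] and (n == node or nx.has_path(g, node, n))
            }
            assert graph.sequenced_descendants(node) == brute


def test_present_everywhere_is_class_one(toy_tree):
    c = classify_mutation(KEY, toy_tree.sequenced, toy_tree, _manifest_from(toy_tree))
    assert c.mutation_class == "I"
    assert c.origin_edge == PRE_REFERENCE
    assert c.activity == "pre_reference"


def test_knockout_private_is_class_three(toy_tree):
    c = classify_mutation(KEY, {"K1"}, toy_tree, _manifest_from(toy_tree))
    assert c.mutation_class == "III"
    assert c.origin_edge == ("P", "K1")
    assert c.activity == "knockout_generation"


def test_knockout_plus_derived_double_is_class_three(toy_tree):
    c = classify_mutation(KEY, {"K2", "K2b"}, toy_tree, _manifest_from(toy_tree))
    assert c.mutation_class == "III"
    assert c.origin_edge == ("P", "K2")


def test_parental_clade_is_class_two_at_earliest_edge(toy_tree):
    """A mutation in every knockout but not the wild type sits on the edge
    that created the parental strain — the earliest consistent transition."""
    c = classify_mutation(KEY, {"K1", "K2", "K2b"}, toy_tree, _manifest_from(toy_tree))
    assert c.mutation_class == "II"
    assert c.origin_edge == ("REF", "P")
    assert c.activity == "parental_generation"
    assert set(c.consistent_edge_range) == {("REF", "P")}


def test_homoplasy_pattern_left_unclassified(toy_tree):
    c = classify_mutation(KEY, {"WT", "K1"}, toy_tree, _manifest_from(toy_tree))
    assert c.mutation_class == "unclassified"
    assert c.homoplasy is True


def test_colony_private_parental_mutation_is_class_two():
    graph = _graph(
        [
            ("REF", "wild_type", False),
            ("P", "parental", True),
            ("K1", "knockout", True),
        ],
        [("REF", "P", "manipulation"), ("P", "K1", "manipulation")],
    )
    c = classify_mutation(KEY, {"P"}, graph, _manifest_from(graph))
    assert c.mutation_class == "II"
    assert c.colony_private is True
    assert c.origin_edge == ("REF", "P")


def test_unsequenced_chain_widens_consistent_range():
    graph = _graph(
        [
            ("REF", "wild_type", False),
            ("WT", "wild_type", True),
            ("P1", "parental", False),
            ("P2", "parental", False),
            ("K", "knockout", True),
        ],
        [
            ("REF", "WT", "transfer"),
            ("REF", "P1", "manipulation"),
            ("P1", "P2", "transfer"),
            ("P2", "K", "manipulation"),
        ],
    )
    c = classify_mutation(KEY, {"K"}, graph, _manifest_from(graph))
    # Every edge below REF towards K is consistent; origin is the earliest.
    assert c.origin_edge == ("REF", "P1")
    assert c.consistent_edge_range == [("REF", "P1"), ("P1", "P2"), ("P2", "K")]
    assert c.mutation_class == "III"  # deepest consistent node is the knockout


def test_origin_matches_exhaustive_edge_oracle(toy_tree):
    """Brute-force check of the consistency predicate over all edges."""
    manifest = _manifest_from(toy_tree)
    patterns = [
        {"K1"}, {"K2"}, {"K2b"}, {"K2", "K2b"}, {"K1", "K2", "K2b"}, {"WT"},
    ]
    for presence in patterns:
        c = classify_mutation(KEY, presence, toy_tree, manifest)
        consistent = [
            (u, v)
            for u, v in toy_tree.graph.edges
            if toy_tree.sequenced_descendants(v) == frozenset(presence)
        ]
        assert set(c.consistent_edge_range) == set(consistent)
        if consistent:
            by_depth = sorted(consistent, key=lambda e: toy_tree.depth(e[1]))
            assert c.origin_edge == by_depth[0]


def test_origin_is_ancestor_of_all_range_edges():
    for seed in range(6):
        graph, manifest = make_lineage(SimConfig(seed=seed))
        for node in graph.graph.nodes:
            presence = graph.sequenced_descendants(node)
            if not presence or presence == graph.sequenced:
                continue
            c = classify_mutation(KEY, presence, graph, manifest)
            if not isinstance(c.origin_edge, tuple):
                continue
            u0 = c.origin_edge[1]
            for _, v in c.consistent_edge_range:
                assert v == u0 or nx.has_path(graph.graph, u0, v)


def test_dropping_a_non_carrier_never_delays_the_origin():
    """Monotonicity: removing a sequenced strain outside the presence set
    can only keep the origin or move it rootward."""
    for seed in range(6):
        graph, manifest = make_lineage(SimConfig(seed=seed))
        nodes = list(graph.graph.nodes)
        for node in nodes:
            presence = graph.sequenced_descendants(node)
            if not presence or presence == graph.sequenced:
                continue
            before = classify_mutation(KEY, presence, graph, manifest)
            if not isinstance(before.origin_edge, tuple):
                continue
            for removed in sorted(graph.sequenced - presence):
                g2 = graph.graph.copy()
                g2.nodes[removed]["sequenced"] = False
                graph2 = LineageGraph(g2)
                after = classify_mutation(KEY, presence, graph2, manifest)
                if after.origin_edge == PRE_REFERENCE:
                    continue  # moved all the way to the root: earliest possible
                assert isinstance(after.origin_edge, tuple)
                # after-origin must be ancestor-or-equal of before-origin.
                u_after, u_before = after.origin_edge[1], before.origin_edge[1]
                assert u_after == u_before or nx.has_path(
                    graph.graph, u_after, u_before
                )


def test_presence_with_unsequenced_strain_rejected(toy_tree):
    with pytest.raises(ValueError):
        classify_mutation(KEY, {"P"}, toy_tree, _manifest_from(toy_tree))


def test_graph_validation():
    with pytest.raises(ValueError):
        _graph(
            [("A", "wild_type", True), ("B", "parental", True)],
            [("A", "B", "manipulation"), ("B", "A", "manipulation")],
        )
    with pytest.raises(ValueError):
        _graph(
            [("A", "wild_type", True), ("B", "wild_type", True)],
            [],  # two roots
        )


def test_lineage_yaml_round_trip(tmp_path, hbt_panel):
    path = tmp_path / "lineage.yaml"
    path.write_text(hbt_panel.graph.to_yaml())
    again = LineageGraph.from_yaml(path)
    assert set(again.graph.nodes) == set(hbt_panel.graph.graph.nodes)
    assert set(again.graph.edges) == set(hbt_panel.graph.graph.edges)
    assert again.sequenced == hbt_panel.graph.sequenced


def test_every_column_receives_exactly_one_class(hfx_result):
    classes = [c.mutation_class for c in hfx_result.classifications]
    assert set(classes) <= {"I", "II", "III", "unclassified"}
    assert len(classes) == len(hfx_result.matrix.key_labels)
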