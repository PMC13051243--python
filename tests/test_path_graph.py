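import json
from collections import Counter
from dataclasses import replace

import pytest

from shaclkit.grouping import group_violations
from shaclkit.kg_io import KGBundle
from shaclkit.path_graph import (
    UNRESOLVED_SHAPES_ID,
    build_path_graph,
    expand_violation_path,
    group_node_id,
    hide_nodes,
)


@pytest.fixture(scope="module")
def lotr_graph(lotr_bundle, lotr_groups):
    return build_path_graph(lotr_bundle, lotr_groups)


def _edge_set(graph):
    return {(e.source, e.target, e.relation) for e in graph.edges}


def test_region_chain_is_present(lotr_graph, lotr_groups):
    region_group = next(g for g in lotr_groups
                        if g.key.source_shape == "lotr:RegionShape-isInContinent")
    gid = group_node_id(region_group.key)
    edges = _edge_set(lotr_graph)
    assert ("lotr:Region", "lotr:RegionShape", "sh:targetClass") in edges
    assert ("lotr:RegionShape", "lotr:RegionShape-isInContinent", "sh:property") in edges
    assert ("lotr:RegionShape-isInContinent", gid, "sh:sourceShape") in edges
    assert (gid, "lotr:MiddleEarth", "sh:value") in edges


def test_node_census(lotr_graph):
    roles = Counter(n.role for n in lotr_graph.nodes)
    assert roles["violation_group"] == 9
    assert roles["instance_object"] == 7
    assert roles["class"] == 6
    assert roles["node_shape"] == 3
    assert roles["property_shape"] == 4


def test_only_violation_values_become_instance_nodes(lotr_graph):
    instance_ids = {n.id for n in lotr_graph.nodes if n.role == "instance_object"}
    assert instance_ids == {"lotr:TheShire", "lotr:MinasTirith", "lotr:Edoras",
                            "lotr:MiddleEarth", "lotr:Eriador", "lotr:Gondor", "lotr:Rohan"}


def test_offending_typed_object_links_back_to_its_class(lotr_graph):
    # regions are offending values that DO carry a type; Middle-earth does not
    edges = _edge_set(lotr_graph)
    assert ("lotr:Eriador", "lotr:Region", "rdf:type") in edges
    assert not any(s == "lotr:MiddleEarth" and r == "rdf:type" for s, t, r in edges)


class TestCumulativeCounts:
    def test_character_shape_accumulates_all_character_violations(self, lotr_graph):
        assert lotr_graph.node("lotr:CharacterShape").count == 17
        assert lotr_graph.node("lotr:Character").count == 17

    def test_property_shape_counts(self, lotr_graph):
        assert lotr_graph.node("lotr:RegionShape-isInContinent").count == 3
        assert lotr_graph.node("lotr:CharacterShape-hasAncestry").count == 5
        assert lotr_graph.node("lotr:CharacterShape-hasHome").count == 12

    def test_class_count_equals_sum_of_group_sizes(self, lotr_graph, lotr_groups):
        total = sum(g.size for g in lotr_groups)
        class_total = sum(n.count for n in lotr_graph.nodes if n.role == "class")
        assert class_total == total == 23

    def test_edges_carry_endpoint_counts(self, lotr_graph):
        counts = {n.id: n.count for n in lotr_graph.nodes}
        for e in lotr_graph.edges:
            assert e.source_count == counts[e.source]
            assert e.target_count == counts[e.target]

    def test_conforming_bundle_all_zero(self, lotr_bundle):
        empty = lotr_bundle.with_report(frozenset())
        graph = build_path_graph(empty, [])
        assert all(n.count == 0 for n in graph.nodes)
        roles = {n.role for n in graph.nodes}
        assert roles <= {"class", "node_shape", "property_shape"}


class TestExpandViolationPath:
    def test_region_expansion_is_the_five_node_chain(self, lotr_graph):
        sub = expand_violation_path(lotr_graph, "lotr:Region")
        assert len(sub.nodes) == 5
        assert {n.role for n in sub.nodes} == {
            "class", "node_shape", "property_shape", "violation_group", "instance_object"}

    def test_character_expansion_has_two_property_shapes_five_groups(self, lotr_graph):
        sub = expand_violation_path(lotr_graph, "lotr:Character")
        roles = Counter(n.role for n in sub.nodes)
        assert roles["property_shape"] == 2
        assert roles["violation_group"] == 5

    def test_violation_free_class_expands_to_itself(self, lotr_graph):
        sub = expand_violation_path(lotr_graph, "lotr:Continent")
        assert [n.id for n in sub.nodes] == ["lotr:Continent"]

    def test_reverse_expansion_from_group_reaches_class(self, lotr_graph, lotr_groups):
        region_group = next(g for g in lotr_groups
                            if g.key.source_shape == "lotr:RegionShape-isInContinent")
        sub = expand_violation_path(lotr_graph, group_node_id(region_group.key))
        ids = {n.id for n in sub.nodes}
        assert "lotr:Region" in ids and "lotr:RegionShape" in ids

    def test_unknown_class_raises(self, lotr_graph):
        with pytest.raises(KeyError):
            expand_violation_path(lotr_graph, "lotr:Mordor")


class TestHideNodes:
    def test_hiding_nothing_is_identity(self, lotr_graph):
        assert hide_nodes(lotr_graph, []) == lotr_graph

    def test_hiding_a_value_removes_incident_edges_not_counts(self, lotr_graph):
        hidden = hide_nodes(lotr_graph, ["lotr:MiddleEarth"])
        assert "lotr:MiddleEarth" not in hidden.node_ids()
        assert not any("lotr:MiddleEarth" in (e.source, e.target) for e in hidden.edges)
        # counts untouched: hiding is visual, not semantic
        assert hidden.node("lotr:RegionShape-isInContinent").count == 3

    def test_hiding_all_groups_leaves_schema_and_instances(self, lotr_graph):
        group_ids = [n.id for n in lotr_graph.nodes if n.role == "violation_group"]
        hidden = hide_nodes(lotr_graph, group_ids)
        assert {n.role for n in hidden.nodes} == {
            "class", "node_shape", "property_shape", "instance_object"}

    def test_unknown_id_ignored_with_warning(self, lotr_graph, caplog):
        import logging
        with caplog.at_level(logging.WARNING):
            hidden = hide_nodes(lotr_graph, ["lotr:Mordor"])
        assert hidden == lotr_graph
        assert any("Mordor" in r.message for r in caplog.records)


def test_every_group_has_exactly_one_incoming_essential_edge(lotr_graph):
    incoming = Counter(e.target for e in lotr_graph.edges
                       if e.essential and e.target.startswith("group:"))
    group_ids = {n.id for n in lotr_graph.nodes if n.role == "violation_group"}
    assert set(incoming) == group_ids
    assert all(c == 1 for c in incoming.values())


def test_orphan_groups_attach_to_unresolved_root(lotr_bundle, lotr_groups):
    shapeless = KGBundle(
        ontology=lotr_bundle.ontology,
        instances=lotr_bundle.instances,
        shapes=frozenset(),
        report=lotr_bundle.report,
        namespaces=lotr_bundle.namespaces,
    )
    graph = build_path_graph(shapeless, lotr_groups, dominant_prefix="lotr")
    assert UNRESOLVED_SHAPES_ID in graph.node_ids()
    for g in lotr_groups:
        assert (UNRESOLVED_SHAPES_ID, group_node_id(g.key), "sh:sourceShape") in _edge_set(graph)


def test_build_is_deterministic(lotr_bundle, lotr_groups):
    a = build_path_graph(lotr_bundle, lotr_groups)
    b = build_path_graph(lotr_bundle, lotr_groups)
    assert a == b
    assert a.to_json() == b.to_json()


def test_json_export_schema(lotr_graph):
    payload = json.loads(lotr_graph.to_json())
    assert set(payload) == {"nodes", "edges"}
    assert {"id", "role", "component", "count", "glyph", "label"} == set(payload["nodes"][0])
    assert {"source", "target", "relation", "essential",
            "source_count", "target_count"} == set(payload["edges"][0])
    # no duplicate (source, target, relation)
    keys = [(e["source"], e["target"], e["relation"]) for e in payload["edges"]]
    assert len(keys) == len(set(keys))
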