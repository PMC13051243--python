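"""Typed node-link graph from classes through shapes to grouped violations.

The graph mirrors how constraint violations attach to a schema: ontology
classes link to the node shapes targeting them, node shapes to their property
shapes, property shapes to the violation groups they produced, and groups to
the concrete offending values.  These four link kinds form the *essential
path*; everything else (subclass links, ``rdf:type`` edges of offending
objects) is context.  Violation counts accumulate along the essential path —
a class's count is the number of violations beneath it — and instance terms
appear only when they are the reported value of at least one violation,
which is what keeps the graph small at scale.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import networkx as nx
from rdflib.namespace import RDF, RDFS, SH

from .class_tree import _declared_classes
from .grouping import NO_VALUE, ViolationGroup
from .kg_io import KGBundle, Term, glyph_category, term_text

log = logging.getLogger(__name__)

_RDF_TYPE = str(RDF.type)
_SUBCLASS = str(RDFS.subClassOf)
_TARGET_CLASS = str(SH.targetClass)
_PROPERTY = str(SH.property)
_NODE_SHAPE = str(SH.NodeShape)
_PROP_SHAPE = str(SH.PropertyShape)

#: Synthetic parent for groups whose source shape is absent from the shapes file.
UNRESOLVED_SHAPES_ID = "⟨unresolved-shapes⟩"

ROLES = ("class", "node_shape", "property_shape", "violation_group", "instance_object", "literal")


@dataclass(frozen=True)
class GraphNode:
    id: str
    role: str
    component: str
    count: int = 0
    glyph: str = "hexagon"
    label: str = ""


@dataclass(frozen=True)
class GraphEdge:
    source: str
    target: str
    relation: str
    essential: bool = False
    source_count: int = 0
    target_count: int = 0


@dataclass
class PathGraph:
    nodes: list[GraphNode] = field(default_factory=list)
    edges: list[GraphEdge] = field(default_factory=list)

    def node_ids(self) -> set[str]:
        return {n.id for n in self.nodes}

    def node(self, node_id: str) -> GraphNode:
        for n in self.nodes:
            if n.id == node_id:
                return n
        raise KeyError(f"no node {node_id!r} in graph")

    def to_nx(self) -> nx.MultiDiGraph:
        g = nx.MultiDiGraph()
        for n in self.nodes:
            g.add_node(n.id, role=n.role, component=n.component, count=n.count,
                       glyph=n.glyph, label=n.label)
        for e in self.edges:
            g.add_edge(e.source, e.target, key=e.relation, relation=e.relation,
                       essential=e.essential, source_count=e.source_count,
                       target_count=e.target_count)
        return g

    def to_json(self) -> str:
        return json.dumps({
            "nodes": [vars(n) for n in self.nodes],
            "edges": [vars(e) for e in self.edges],
        }, indent=2, ensure_ascii=False)


def group_node_id(key) -> str:
    """Deterministic group-node id: a short hash of the key text."""
    text = f"{key.source_shape}|{key.message}|{key.value}"
    return "group:" + hashlib.sha256(text.encode("utf-8")).hexdigest()[:12]


def _dominant_prefix(bundle: KGBundle) -> str:
    """The prefix compacting the most ontology class IRIs; the table's first
    prefix when the ontology names none."""
    classes, _ = _declared_classes(bundle.ontology, bundle.namespaces)
    votes: dict[str, int] = {}
    for c in classes:
        if ":" in c and "://" not in c:
            votes[c.split(":", 1)[0]] = votes.get(c.split(":", 1)[0], 0) + 1
    for special in ("sh", "rdf", "rdfs", "owl", "xsd", "ex"):
        votes.pop(special, None)
    if votes:
        return max(sorted(votes), key=lambda p: votes[p])
    return next(iter(bundle.namespaces))


def build_path_graph(
    bundle: KGBundle,
    groups: Sequence[ViolationGroup],
    dominant_prefix: Optional[str] = None,
) -> PathGraph:
    """Assemble the full class → shape → group → value graph.

    Node and edge ordering is deterministic.  Counts are filled by
    :func:`cumulative_counts`, which is applied before returning.
    """
    ns = bundle.namespaces
    dom = dominant_prefix or _dominant_prefix(bundle)

    nodes: dict[str, GraphNode] = {}
    edges: dict[tuple[str, str, str], GraphEdge] = {}

    def add_node(node: GraphNode) -> None:
        nodes.setdefault(node.id, node)

    def add_edge(source: str, target: str, relation: str, essential: bool) -> None:
        edges.setdefault((source, target, relation), GraphEdge(source, target, relation, essential))

    def glyph_of(term: Term) -> str:
        return glyph_category(term, ns, dom)

    # --- ontology: classes and subclass links
    classes, parent_map = _declared_classes(bundle.ontology, ns)
    for c in classes:
        add_node(GraphNode(id=c, role="class", component="ontology", glyph="circle", label=c))
    for child, parents in parent_map.items():
        for parent in parents:
            add_edge(child, parent, "rdfs:subClassOf", essential=False)

    # --- shapes: node shapes (via sh:targetClass / rdf:type) and property shapes
    shape_idx: dict[Term, dict[str, list[Term]]] = {}
    for t in bundle.shapes:
        shape_idx.setdefault(t.subject, {}).setdefault(t.predicate.value, []).append(t.object)

    node_shapes = [
        s for s, po in shape_idx.items()
        if _TARGET_CLASS in po or any(o.value == _NODE_SHAPE for o in po.get(_RDF_TYPE, ()))
    ]
    prop_of_shape: dict[str, list[str]] = {}
    for s in node_shapes:
        sid = term_text(s, ns)
        add_node(GraphNode(id=sid, role="node_shape", component="shapes",
                           glyph=glyph_of(s), label=sid))
        for target in shape_idx[s].get(_TARGET_CLASS, ()):
            tid = term_text(target, ns)
            add_node(GraphNode(id=tid, role="class", component="ontology", glyph="circle", label=tid))
            add_edge(tid, sid, "sh:targetClass", essential=True)
        for prop in shape_idx[s].get(_PROPERTY, ()):
            pid = term_text(prop, ns)
            add_node(GraphNode(id=pid, role="property_shape", component="shapes",
                               glyph=glyph_of(prop), label=pid))
            add_edge(sid, pid, "sh:property", essential=True)
            prop_of_shape.setdefault(pid, []).append(sid)

    known_shape_ids = {term_text(s, ns) for s in shape_idx}

    # --- violation groups and their offending values
    instance_types: dict[str, list[str]] = {}
    for t in bundle.instances:
        if t.predicate.value == _RDF_TYPE:
            instance_types.setdefault(term_text(t.subject, ns), []).append(term_text(t.object, ns))

    for g in sorted(groups, key=lambda g: g.key):
        gid = group_node_id(g.key)
        label = f"{g.key.source_shape} = {g.key.value} ({g.size})"
        add_node(GraphNode(id=gid, role="violation_group", component="report",
                           count=g.size, glyph="triangle", label=label))
        shape_id = g.key.source_shape
        if shape_id in known_shape_ids:
            add_edge(shape_id, gid, "sh:sourceShape", essential=True)
        else:
            log.warning("group %s has source shape %s absent from the shapes component",
                        gid, shape_id)
            add_node(GraphNode(id=UNRESOLVED_SHAPES_ID, role="node_shape", component="shapes",
                               glyph="square", label=UNRESOLVED_SHAPES_ID))
            add_edge(UNRESOLVED_SHAPES_ID, gid, "sh:sourceShape", essential=True)

        if g.key.value != NO_VALUE:
            value_term = g.exemplar.value
            vid = g.key.value
            role = "literal" if (value_term is not None and value_term.is_literal) else "instance_object"
            add_node(GraphNode(id=vid, role=role, component="instance",
                               glyph=glyph_of(value_term) if value_term is not None else "hexagon",
                               label=vid))
            add_edge(gid, vid, "sh:value", essential=True)
            # context edges: the offending object's asserted types (their
            # absence is itself diagnostic — a value with no type edge back to
            # the expected class is the classic root cause)
            for cls in instance_types.get(vid, ()):
                if cls in nodes:
                    add_edge(vid, cls, "rdf:type", essential=False)

    graph = PathGraph(
        nodes=[nodes[k] for k in sorted(nodes)],
        edges=[edges[k] for k in sorted(edges)],
    )
    return cumulative_counts(graph)


def cumulative_counts(graph: PathGraph) -> PathGraph:
    """Propagate group sizes up the essential path and onto edge endpoints.

    property shape = Σ its groups; node shape = Σ its property shapes;
    class = Σ its node shapes.  Group counts are taken as given.
    """
    counts = {n.id: (n.count if n.role == "violation_group" else 0) for n in graph.nodes}
    roles = {n.id: n.role for n in graph.nodes}

    essential_children: dict[str, list[str]] = {}
    for e in graph.edges:
        if e.essential:
            essential_children.setdefault(e.source, []).append(e.target)

    def total(node_id: str) -> int:
        if roles[node_id] in ("violation_group", "instance_object", "literal"):
            return counts[node_id]
        return sum(total(child) for child in essential_children.get(node_id, ()))

    for n in graph.nodes:
        if roles[n.id] in ("class", "node_shape", "property_shape"):
            counts[n.id] = total(n.id)

    new_nodes = [
        replace(n, count=counts[n.id], label=_with_count(n, counts[n.id]))
        for n in graph.nodes
    ]
    new_edges = [
        replace(e, source_count=counts[e.source], target_count=counts[e.target])
        for e in graph.edges
    ]
    return PathGraph(nodes=new_nodes, edges=new_edges)


def _with_count(node: GraphNode, count: int) -> str:
    base = node.label.rsplit(" (", 1)[0] if node.label.endswith(")") else node.label
    if node.role == "violation_group":
        return node.label  # group labels already carry their size
    return f"{base} ({count})"


def expand_violation_path(graph: PathGraph, start_id: str) -> PathGraph:
    """Induced subgraph of everything essential-path-reachable from a node.

    From a class this walks down (node shapes, property shapes, groups,
    values); from any other node — e.g., a violation group — it walks the
    reversed essential edges up to the class, which is the navigation the
    class↔violation drill-down requires in both directions.
    """
    ids = graph.node_ids()
    if start_id not in ids:
        raise KeyError(f"unknown node {start_id!r}")
    forward = graph.node(start_id).role == "class"

    adjacency: dict[str, list[str]] = {}
    for e in graph.edges:
        if not e.essential:
            continue
        if forward:
            adjacency.setdefault(e.source, []).append(e.target)
        else:
            adjacency.setdefault(e.target, []).append(e.source)

    reach = {start_id}
    frontier = [start_id]
    while frontier:
        current = frontier.pop()
        for nxt in adjacency.get(current, ()):
            if nxt not in reach:
                reach.add(nxt)
                frontier.append(nxt)
    return _induced(graph, reach)


def hide_nodes(graph: PathGraph, ids: Iterable[str]) -> PathGraph:
    """Drop the given nodes and their incident edges; counts are left as they
    were (hiding is a presentation operation, not a recomputation)."""
    ids = set(ids)
    unknown = ids - graph.node_ids()
    for node_id in sorted(unknown):
        log.warning("hide_nodes: ignoring unknown node %r", node_id)
    return _induced(graph, graph.node_ids() - ids)


def _induced(graph: PathGraph, keep: set[str]) -> PathGraph:
    return PathGraph(
        nodes=[n for n in graph.nodes if n.id in keep],
        edges=[e for e in graph.edges if e.source in keep and e.target in keep],
    )
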