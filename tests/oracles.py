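"""Independent test oracles, deliberately written against rdflib graphs —
not the package's Triple sets — so they share no code path with the
implementations they check."""
from __future__ import annotations

from rdflib import Graph
from rdflib.namespace import RDF, SH

from shaclkit.grouping import NO_VALUE, normalize_message
from shaclkit.kg_io import KGBundle, graph_from_triples, term_text


def oracle_validate(bundle: KGBundle) -> set[tuple[str, str, str | None]]:
    """Full SHACL-subset validation by direct rdflib graph traversal.

    Returns the set of (focus IRI, property-shape IRI, value IRI or None);
    messages are deliberately excluded from the comparison surface.
    """
    shapes: Graph = graph_from_triples(bundle.shapes)
    data: Graph = graph_from_triples(bundle.instances)
    known_shapes = set(shapes.subjects(SH.targetClass, None))

    def conforms(node, node_shape) -> bool:
        for prop in shapes.objects(node_shape, SH.property):
            path = shapes.value(prop, SH.path)
            values = list(data.objects(node, path))
            min_count = shapes.value(prop, SH.minCount)
            if min_count is not None and len(values) < int(min_count):
                return False
            required_class = shapes.value(prop, SH["class"])
            if required_class is not None:
                if any((v, RDF.type, required_class) not in data for v in values):
                    return False
            inner = shapes.value(prop, SH.node)
            if inner is not None and inner in known_shapes:
                if any(not conforms(v, inner) for v in values):
                    return False
        return True

    results: set[tuple[str, str, str | None]] = set()
    for node_shape in known_shapes:
        for target in shapes.objects(node_shape, SH.targetClass):
            for focus in data.subjects(RDF.type, target):
                for prop in shapes.objects(node_shape, SH.property):
                    path = shapes.value(prop, SH.path)
                    values = list(data.objects(focus, path))
                    min_count = shapes.value(prop, SH.minCount)
                    if min_count is not None and len(values) < int(min_count):
                        results.add((str(focus), str(prop), None))
                    required_class = shapes.value(prop, SH["class"])
                    if required_class is not None:
                        for v in values:
                            if (v, RDF.type, required_class) not in data:
                                results.add((str(focus), str(prop), str(v)))
                    inner = shapes.value(prop, SH.node)
                    if inner is not None and inner in known_shapes:
                        for v in values:
                            if not conforms(v, inner):
                                results.add((str(focus), str(prop), str(v)))
    return results


def record_signature(records, ns) -> set[tuple[str, str, str | None]]:
    """Project parsed violation records onto the oracle's comparison surface."""
    return {
        (
            r.focus_node.value,
            r.source_shape.value,
            r.value.value if r.value is not None else None,
        )
        for r in records
    }


def brute_force_partition(records, ns) -> set[frozenset[int]]:
    """Grouping by exhaustive pairwise equivalence comparison (quadratic);
    returns the partition as index sets, which is representation-free."""

    def equivalent(a, b) -> bool:
        value_a = term_text(a.value, ns) if a.value is not None else NO_VALUE
        value_b = term_text(b.value, ns) if b.value is not None else NO_VALUE
        return (
            term_text(a.source_shape, ns) == term_text(b.source_shape, ns)
            and normalize_message(a.message) == normalize_message(b.message)
            and value_a == value_b
        )

    records = list(records)
    assigned: dict[int, set[int]] = {}
    parts: list[set[int]] = []
    for i, record in enumerate(records):
        for part in parts:
            if equivalent(records[next(iter(part))], record):
                part.add(i)
                break
        else:
            parts.append({i})
    return {frozenset(p) for p in parts}
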