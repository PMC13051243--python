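"""Class-hierarchy forest with per-class violating-focus-node counts.

The ontology's ``rdfs:subClassOf`` statements are turned into a forest whose
nodes carry ``n/m`` labels: m counts the distinct violating focus nodes whose
direct asserted type is that class, n the subset inside the current
selection.  Classes that appear as asserted instance types but are undeclared
in the ontology surface in a separate *Missing* bracket — these are exactly
the schema gaps curators need to see.

Counts use direct ``rdf:type`` assertions only (no RDFS inference, no
subclass rollup); a cumulative per-subtree total is exported alongside.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from rdflib.namespace import OWL, RDF, RDFS

from .grouping import FocusIndex
from .kg_io import NamespaceTable, Triple

_RDF_TYPE = str(RDF.type)
_SUBCLASS = str(RDFS.subClassOf)
_CLASS_TYPES = {str(RDFS.Class), str(OWL.Class)}


class ClassCycleError(ValueError):
    """The ontology's subclass relation contains a cycle."""


@dataclass
class ClassTreeNode:
    class_iri: str  # compacted
    children: list["ClassTreeNode"] = field(default_factory=list)
    m: int = 0
    n: int = 0
    missing: bool = False
    subtree_total: int = 0
    #: additional superclasses when the class has several parents; the node is
    #: attached under its lexicographically first parent and cross-listed here.
    also_under: list[str] = field(default_factory=list)

    def walk(self) -> Iterable["ClassTreeNode"]:
        yield self
        for child in self.children:
            yield from child.walk()

    def label(self) -> str:
        return f"{self.class_iri} ({self.n}/{self.m})"


def _declared_classes(ontology: Iterable[Triple], ns: NamespaceTable) -> tuple[set[str], dict[str, list[str]]]:
    """All declared classes and the child → parents map, compacted."""
    classes: set[str] = set()
    parents: dict[str, list[str]] = {}
    for t in ontology:
        if t.predicate.value == _SUBCLASS and t.object.kind == "iri" and t.subject.kind == "iri":
            child = ns.compact(t.subject.value)
            parent = ns.compact(t.object.value)
            classes.update((child, parent))
            parents.setdefault(child, []).append(parent)
        elif t.predicate.value == _RDF_TYPE and t.object.value in _CLASS_TYPES and t.subject.kind == "iri":
            classes.add(ns.compact(t.subject.value))
    return classes, parents


def build_class_tree(ontology: Iterable[Triple], ns: NamespaceTable) -> list[ClassTreeNode]:
    """Build the subclass forest; roots are classes with no declared parent.

    A class with several parents is attached under its lexicographically
    first parent and cross-listed (by name) on the node's ``also_under``.
    A subclass cycle raises :class:`ClassCycleError` naming the cycle.
    """
    classes, parents = _declared_classes(ontology, ns)

    # cycle check over the full (multi-)parent relation
    WHITE, GRAY, BLACK = 0, 1, 2
    color = {c: WHITE for c in classes}

    def visit(node: str, stack: list[str]) -> None:
        color[node] = GRAY
        stack.append(node)
        for parent in parents.get(node, ()):
            if color[parent] == GRAY:
                cycle = stack[stack.index(parent):] + [parent]
                raise ClassCycleError(f"rdfs:subClassOf cycle: {' < '.join(cycle)}")
            if color[parent] == WHITE:
                visit(parent, stack)
        stack.pop()
        color[node] = BLACK

    for c in sorted(classes):
        if color[c] == WHITE:
            visit(c, [])

    nodes = {c: ClassTreeNode(class_iri=c) for c in classes}
    roots: list[ClassTreeNode] = []
    for c in sorted(classes):
        ps = sorted(set(parents.get(c, ())))
        if ps:
            nodes[ps[0]].children.append(nodes[c])
            nodes[c].also_under = ps[1:]
        else:
            roots.append(nodes[c])
    for node in nodes.values():
        node.children.sort(key=lambda n: n.class_iri)
    roots.sort(key=lambda n: n.class_iri)
    return roots


def annotate_counts(
    forest: Sequence[ClassTreeNode],
    focus_index: FocusIndex,
    selection: Optional[Iterable[str]] = None,
) -> Sequence[ClassTreeNode]:
    """Fill n/m (and subtree totals) in place; structure is never changed.

    m per class = distinct violating focus nodes directly typed with it;
    n = those inside the selection (0 when no selection is given).  A focus
    node with k asserted types contributes to k classes.
    """
    selected = set(selection) if selection is not None else set()
    by_class: dict[str, set[str]] = {}
    for focus, entry in focus_index.items():
        for cls in entry.classes:
            by_class.setdefault(cls, set()).add(focus)

    def fill(node: ClassTreeNode) -> int:
        members = by_class.get(node.class_iri, set())
        node.m = len(members)
        node.n = len(members & selected)
        node.subtree_total = node.m + sum(fill(child) for child in node.children)
        return node.subtree_total

    for root in forest:
        fill(root)
    return forest


def missing_classes(
    instance_triples: Iterable[Triple],
    forest: Sequence[ClassTreeNode],
    focus_index: FocusIndex,
    ns: NamespaceTable,
) -> list[ClassTreeNode]:
    """The *Missing* bracket: classes asserted as instance types but absent
    from the ontology forest, with m counted over violating focus nodes."""
    declared = {node.class_iri for root in forest for node in root.walk()}
    asserted: set[str] = set()
    for t in instance_triples:
        if t.predicate.value == _RDF_TYPE and t.object.kind == "iri":
            asserted.add(ns.compact(t.object.value))

    by_class: dict[str, set[str]] = {}
    for focus, entry in focus_index.items():
        for cls in entry.classes:
            by_class.setdefault(cls, set()).add(focus)

    bracket = []
    for cls in sorted(asserted - declared):
        node = ClassTreeNode(class_iri=cls, missing=True)
        node.m = len(by_class.get(cls, ()))
        node.subtree_total = node.m
        bracket.append(node)
    return bracket


def _node_dict(node: ClassTreeNode) -> dict:
    return {
        "class": node.class_iri,
        "n": node.n,
        "m": node.m,
        "missing": node.missing,
        "subtree_total": node.subtree_total,
        "also_under": node.also_under,
        "children": [_node_dict(c) for c in node.children],
    }


def tree_to_json(forest: Sequence[ClassTreeNode], bracket: Sequence[ClassTreeNode] = ()) -> str:
    return json.dumps(
        {"roots": [_node_dict(n) for n in forest], "missing": [_node_dict(n) for n in bracket]},
        indent=2,
        ensure_ascii=False,
    )
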