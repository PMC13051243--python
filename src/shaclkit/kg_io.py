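"""Parsing, tagging, and serialization of the four-component RDF input set.

A curation run operates on up to four RDF graphs, conventionally shipped as
Turtle files: the ontology (RDFS classes and ``rdfs:subClassOf`` links),
instance data (typed individuals), SHACL shapes, and an optional SHACL
validation report.  Component membership is recorded per source file — never
inferred from vocabulary — because shapes and ontology terms may legally share
namespaces and even files.

Terms and triples are held in small immutable dataclasses so that downstream
modules can use them as dictionary and set keys; conversion to and from
:mod:`rdflib` happens only at the I/O boundary.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Optional

import rdflib
from rdflib import BNode, Graph, URIRef
from rdflib import Literal as RdfLiteral
from rdflib.namespace import OWL, RDF, RDFS, SH, XSD

log = logging.getLogger(__name__)

COMPONENTS = ("ontology", "instances", "shapes", "report")

#: Namespaces every table carries, so core vocabulary always compacts.
BASE_NAMESPACES = {
    "rdf": str(RDF),
    "rdfs": str(RDFS),
    "sh": str(SH),
    "owl": str(OWL),
    "xsd": str(XSD),
}


class BundleInputError(ValueError):
    """A required input file is missing or unreadable."""


class BundleParseError(ValueError):
    """A Turtle document failed to parse."""


@dataclass(frozen=True, order=True)
class Term:
    """One RDF term: an IRI, a blank node, or a literal.

    Literal identity is (value, datatype, language) — lexical identity, not
    value-space equality — so grouping keys are reproducible without datatype
    arithmetic.
    """

    kind: str  # "iri" | "blank" | "literal"
    value: str
    datatype: Optional[str] = None
    language: Optional[str] = None

    def __post_init__(self) -> None:
        if self.kind not in ("iri", "blank", "literal"):
            raise ValueError(f"unknown term kind {self.kind!r}")
        if self.kind != "literal" and (self.datatype or self.language):
            raise ValueError("datatype/language are only valid on literals")
        if self.datatype and self.language:
            raise ValueError("datatype and language are mutually exclusive")

    @property
    def is_literal(self) -> bool:
        return self.kind == "literal"


def iri(value: str) -> Term:
    return Term("iri", value)


def blank(label: str) -> Term:
    return Term("blank", label)


def literal(value: str, datatype: str | None = None, language: str | None = None) -> Term:
    return Term("literal", value, datatype=datatype, language=language)


@dataclass(frozen=True, order=True)
class Triple:
    subject: Term
    predicate: Term
    object: Term

    def __post_init__(self) -> None:
        if self.predicate.kind != "iri":
            raise ValueError("triple predicate must be an IRI")
        if self.subject.kind == "literal":
            raise ValueError("triple subject cannot be a literal")


class NamespaceTable(Mapping[str, str]):
    """Prefix → namespace-IRI mapping with longest-match compaction.

    The first binding of a prefix wins; later conflicting bindings are logged
    and ignored so that merging files with divergent prefix conventions is
    never fatal.
    """

    def __init__(self, mapping: Mapping[str, str] | None = None) -> None:
        self._map: dict[str, str] = dict(BASE_NAMESPACES)
        if mapping:
            for prefix, ns in mapping.items():
                self.add(prefix, ns)

    def add(self, prefix: str, namespace: str, source: str = "") -> None:
        if not namespace:
            raise ValueError("namespace IRI must be non-empty")
        existing = self._map.get(prefix)
        if existing is None:
            self._map[prefix] = namespace
        elif existing != namespace:
            log.warning(
                "prefix %r already bound to <%s>; ignoring conflicting binding <%s>%s",
                prefix, existing, namespace, f" from {source}" if source else "",
            )

    # Mapping protocol -----------------------------------------------------
    def __getitem__(self, prefix: str) -> str:
        return self._map[prefix]

    def __iter__(self) -> Iterator[str]:
        return iter(self._map)

    def __len__(self) -> int:
        return len(self._map)

    # Compaction -----------------------------------------------------------
    def _namespace_to_prefix(self) -> dict[str, str]:
        # When two prefixes share a namespace the lexicographically smallest
        # prefix is used, keeping compaction deterministic and injective.
        rev: dict[str, str] = {}
        for prefix in sorted(self._map):
            rev.setdefault(self._map[prefix], prefix)
        return rev

    def compact(self, iri_text: str) -> str:
        """Compact a full IRI to ``prefix:local`` under the longest matching
        namespace; the IRI is returned verbatim when nothing matches."""
        best_ns = ""
        for ns in self._map.values():
            if iri_text.startswith(ns) and len(ns) > len(best_ns) and iri_text != ns:
                best_ns = ns
        if not best_ns:
            return iri_text
        prefix = self._namespace_to_prefix()[best_ns]
        return f"{prefix}:{iri_text[len(best_ns):]}"

    def prefix_of(self, iri_text: str) -> Optional[str]:
        """The prefix the IRI compacts under, or None."""
        compacted = self.compact(iri_text)
        if compacted == iri_text:
            return None
        return compacted.split(":", 1)[0]

    def to_json(self) -> str:
        return json.dumps(dict(sorted(self._map.items())), indent=2)

    def copy(self) -> "NamespaceTable":
        return NamespaceTable(self._map)


def compact(term: Term, ns: NamespaceTable) -> str:
    """``prefix:local`` form of an IRI term (full IRI when no prefix matches)."""
    if term.kind != "iri":
        raise ValueError("compact() expects an IRI term")
    return ns.compact(term.value)


def term_text(term: Term, ns: NamespaceTable) -> str:
    """Deterministic, human-readable rendering of any term.

    IRIs are compacted, blank nodes get the ``_:`` convention, literals a
    Turtle-like quoted form.  Used as the canonical keying text throughout.
    """
    if term.kind == "iri":
        return ns.compact(term.value)
    if term.kind == "blank":
        return f"_:{term.value}"
    text = f'"{term.value}"'
    if term.language:
        return f"{text}@{term.language}"
    if term.datatype and term.datatype != str(XSD.string):
        return f"{text}^^{ns.compact(term.datatype)}"
    return text


def glyph_category(term: Term, ns: NamespaceTable, dominant_prefix: str) -> str:
    """Map a term to one of five glyph classes by namespace.

    SHACL vocabulary → ``square``; the dominant ontology namespace →
    ``circle``; the ``ex:`` exemplar namespace → ``triangle``; OWL →
    ``diamond``; literals, blank nodes, and all remaining namespaces →
    ``hexagon``.
    """
    if dominant_prefix not in ns:
        raise KeyError(f"dominant prefix {dominant_prefix!r} not in namespace table")
    if term.kind != "iri":
        return "hexagon"
    prefix = ns.prefix_of(term.value)
    if prefix == "sh":
        return "square"
    if prefix == dominant_prefix:
        return "circle"
    if prefix == "ex":
        return "triangle"
    if prefix == "owl":
        return "diamond"
    return "hexagon"


# rdflib bridge ------------------------------------------------------------

def term_from_rdflib(node: rdflib.term.Node) -> Term:
    if isinstance(node, URIRef):
        return Term("iri", str(node))
    if isinstance(node, BNode):
        return Term("blank", str(node))
    if isinstance(node, RdfLiteral):
        return Term(
            "literal",
            str(node),
            datatype=str(node.datatype) if node.datatype else None,
            language=node.language,
        )
    raise TypeError(f"unsupported rdflib node {node!r}")


def term_to_rdflib(term: Term) -> rdflib.term.Node:
    if term.kind == "iri":
        return URIRef(term.value)
    if term.kind == "blank":
        return BNode(term.value)
    return RdfLiteral(
        term.value,
        datatype=URIRef(term.datatype) if term.datatype else None,
        lang=term.language,
    )


def triples_from_graph(graph: Graph) -> frozenset[Triple]:
    return frozenset(
        Triple(term_from_rdflib(s), term_from_rdflib(p), term_from_rdflib(o))
        for s, p, o in graph
    )


def graph_from_triples(triples: Iterable[Triple], ns: NamespaceTable | None = None) -> Graph:
    graph = Graph()
    if ns is not None:
        for prefix, namespace in ns.items():
            graph.bind(prefix, namespace, override=False)
    for t in triples:
        graph.add((term_to_rdflib(t.subject), term_to_rdflib(t.predicate), term_to_rdflib(t.object)))
    return graph


@dataclass(frozen=True)
class KGBundle:
    """The four tagged components of one analysis input set.

    The report component may be empty (data not yet validated); the other
    three are the validation inputs.  A shared namespace table covers every
    prefix needed to compact any IRI in any component.
    """

    ontology: frozenset[Triple] = frozenset()
    instances: frozenset[Triple] = frozenset()
    shapes: frozenset[Triple] = frozenset()
    report: frozenset[Triple] = frozenset()
    namespaces: NamespaceTable = field(default_factory=NamespaceTable)

    def component(self, name: str) -> frozenset[Triple]:
        if name not in COMPONENTS:
            raise KeyError(f"unknown component {name!r}")
        return getattr(self, name)

    def component_graph(self, name: str) -> Graph:
        return graph_from_triples(self.component(name), self.namespaces)

    def serialize_component(self, name: str) -> str:
        return self.component_graph(name).serialize(format="turtle")

    def with_report(self, report: Iterable[Triple]) -> "KGBundle":
        return replace(self, report=frozenset(report))

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Write each non-empty component as ``<component>.ttl`` under out_dir."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        written: dict[str, Path] = {}
        for name in COMPONENTS:
            triples = self.component(name)
            if name == "report" and not triples:
                continue
            path = out / f"{name}.ttl"
            path.write_text(self.serialize_component(name), encoding="utf-8")
            written[name] = path
        return written


def _parse_turtle(path: str | Path, component: str) -> Graph:
    path = Path(path)
    if not path.is_file():
        raise BundleInputError(f"cannot read {component} file: {path}")
    graph = Graph()
    try:
        graph.parse(path, format="turtle")
    except Exception as exc:  # rdflib's BadSyntax carries the line number
        raise BundleParseError(f"Turtle syntax error in {path}: {exc}") from exc
    return graph


def parse_bundle(
    ontology_path: str | Path,
    instances_path: str | Path,
    shapes_path: str | Path,
    report_path: str | Path | None = None,
) -> KGBundle:
    """Parse up to four Turtle files into a tagged :class:`KGBundle`.

    Namespace tables of the files are merged with first-definition-wins
    semantics; a prefix bound to two different IRIs across files is logged as
    a warning, never fatal.
    """
    paths = {
        "ontology": ontology_path,
        "instances": instances_path,
        "shapes": shapes_path,
    }
    if report_path is not None:
        paths["report"] = report_path

    ns = NamespaceTable()
    components: dict[str, frozenset[Triple]] = {}
    for name, path in paths.items():
        graph = _parse_turtle(path, name)
        for prefix, namespace in graph.namespaces():
            if prefix:  # skip the default ("") prefix; it is file-local
                ns.add(str(prefix), str(namespace), source=str(path))
        components[name] = triples_from_graph(graph)

    return KGBundle(
        ontology=components["ontology"],
        instances=components["instances"],
        shapes=components["shapes"],
        report=components.get("report", frozenset()),
        namespaces=ns,
    )
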