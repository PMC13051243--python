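"""Synthetic knowledge-graph bundles and a mini SHACL validator.

The guiding fixture is a small Tolkien-themed KG engineered to exhibit the
violation anatomy real curation data shows: a missing class assignment on a
single hub node (Middle-earth is never typed as a Continent) cascades through
``sh:node`` conformance down to regions, locations, and finally characters'
homes; a whole cohort (the Hobbits) shares one missing-property violation;
and a couple of characters simply lack a required property.  Defaults
reproduce the canonical counts: 5 Hobbits, 7 other violating characters,
3 locations, 3 regions — 23 violation records over 18 focus nodes.

The bundled validator implements standard SHACL semantics for exactly the
constraint subset the fixtures use — ``sh:minCount``, ``sh:class``,
``sh:node`` — so the whole pipeline is testable hermetically, and its record
sets are cross-checked in the test suite against an independently written
validator.
"""
from __future__ import annotations

import random
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from rdflib.namespace import RDF, RDFS, SH, XSD

from .kg_io import KGBundle, NamespaceTable, Term, Triple, blank, iri, literal

LOTR_NS = "http://example.org/lotr#"
EX_NS = "http://example.org/ex#"
SYN_NS = "http://example.org/synthetic#"

_RDF_TYPE = str(RDF.type)

_SUPPORTED_SHAPE_PREDICATES = {
    str(SH.path), str(SH.minCount), str(SH["class"]), str(SH.node),
    str(SH.message), str(SH.name), str(SH.description), _RDF_TYPE,
}

_COMPONENT_MIN_COUNT = str(SH.MinCountConstraintComponent)
_COMPONENT_CLASS = str(SH.ClassConstraintComponent)
_COMPONENT_NODE = str(SH.NodeConstraintComponent)


class FixtureConfigError(ValueError):
    pass


class UnsupportedConstraintError(ValueError):
    """A shape uses a constraint component outside {minCount, class, node}."""


class ShapeCycleError(ValueError):
    """The sh:node conformance graph is cyclic."""


@dataclass(frozen=True)
class PropertyDef:
    shape_iri: str
    path: str
    message: str
    min_count: Optional[int] = None
    class_constraint: Optional[str] = None
    node_constraint: Optional[str] = None

    def __post_init__(self) -> None:
        if self.min_count is None and self.class_constraint is None and self.node_constraint is None:
            raise ValueError(f"property shape {self.shape_iri} declares no constraint")


@dataclass(frozen=True)
class ShapeDef:
    node_shape: str
    target_class: str
    properties: tuple[PropertyDef, ...]


@dataclass(frozen=True)
class FixtureConfig:
    """Knobs of the guiding fixture; the defaults ARE the canonical dataset."""

    n_hobbits: int = 5
    n_other_characters: int = 7
    n_missing_home: int = 2
    n_locations: int = 3
    n_regions: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_hobbits, self.n_other_characters, self.n_locations, self.n_regions) < 0:
            raise FixtureConfigError("counts must be non-negative")
        if self.n_missing_home > self.n_other_characters:
            raise FixtureConfigError("n_missing_home cannot exceed n_other_characters")
        if self.n_regions != self.n_locations:
            raise FixtureConfigError(
                "the default cascade topology pairs each location with its own region"
            )


_HOBBITS = ["Frodo", "Samwise", "Meriadoc", "Peregrin", "Bilbo"]
_OTHERS = ["Aragorn", "Boromir", "Faramir", "Eowyn", "Theoden", "Gimli", "Legolas"]
_LOCATIONS = ["TheShire", "MinasTirith", "Edoras"]
_REGIONS = ["Eriador", "Gondor", "Rohan"]
_ANCESTRIES = ["MenOfGondor", "MenOfRohan", "Dwarves", "Elves"]


def _names(base: Sequence[str], n: int, stem: str) -> list[str]:
    names = list(base[:n])
    names += [f"{stem}{i + 1}" for i in range(len(names), n)]
    return names


def _xsd_int(n: int) -> Term:
    return literal(str(n), datatype=str(XSD.integer))


def _shape_triples(defs: Iterable[ShapeDef], ns_iri: str) -> set[Triple]:
    triples: set[Triple] = set()
    for sd in defs:
        node_shape = iri(sd.node_shape)
        triples.add(Triple(node_shape, iri(_RDF_TYPE), iri(str(SH.NodeShape))))
        triples.add(Triple(node_shape, iri(str(SH.targetClass)), iri(sd.target_class)))
        for p in sd.properties:
            prop = iri(p.shape_iri)
            triples.add(Triple(node_shape, iri(str(SH.property)), prop))
            triples.add(Triple(prop, iri(_RDF_TYPE), iri(str(SH.PropertyShape))))
            triples.add(Triple(prop, iri(str(SH.path)), iri(p.path)))
            triples.add(Triple(prop, iri(str(SH.message)), literal(p.message)))
            if p.min_count is not None:
                triples.add(Triple(prop, iri(str(SH.minCount)), _xsd_int(p.min_count)))
            if p.class_constraint is not None:
                triples.add(Triple(prop, iri(str(SH["class"])), iri(p.class_constraint)))
            if p.node_constraint is not None:
                triples.add(Triple(prop, iri(str(SH.node)), iri(p.node_constraint)))
    return triples


def _lotr_shape_defs() -> list[ShapeDef]:
    L = LOTR_NS
    return [
        ShapeDef(
            node_shape=f"{L}CharacterShape",
            target_class=f"{L}Character",
            properties=(
                PropertyDef(
                    shape_iri=f"{L}CharacterShape-hasAncestry",
                    path=f"{L}hasAncestry",
                    min_count=1,
                    class_constraint=f"{L}Ancestry",
                    message="Character must have an ancestry of class Ancestry.",
                ),
                PropertyDef(
                    shape_iri=f"{L}CharacterShape-hasHome",
                    path=f"{L}hasHome",
                    min_count=1,
                    node_constraint=f"{L}LocationShape",
                    message="Character must have a home that is a valid location.",
                ),
            ),
        ),
        ShapeDef(
            node_shape=f"{L}LocationShape",
            target_class=f"{L}Location",
            properties=(
                PropertyDef(
                    shape_iri=f"{L}LocationShape-isInRegion",
                    path=f"{L}isInRegion",
                    min_count=1,
                    node_constraint=f"{L}RegionShape",
                    message="Location must be in a valid region.",
                ),
            ),
        ),
        ShapeDef(
            node_shape=f"{L}RegionShape",
            target_class=f"{L}Region",
            properties=(
                PropertyDef(
                    shape_iri=f"{L}RegionShape-isInContinent",
                    path=f"{L}isInContinent",
                    min_count=1,
                    class_constraint=f"{L}Continent",
                    message="Region must be in a continent.",
                ),
            ),
        ),
    ]


def _lotr_namespaces() -> NamespaceTable:
    return NamespaceTable({"lotr": LOTR_NS, "ex": EX_NS})


def _lotr_ontology() -> set[Triple]:
    L = LOTR_NS
    triples: set[Triple] = set()
    classes = ["Thing", "Character", "Ancestry", "Location", "Region", "Continent"]
    for name in classes:
        triples.add(Triple(iri(f"{L}{name}"), iri(_RDF_TYPE), iri(str(RDFS.Class))))
        if name != "Thing":
            triples.add(Triple(iri(f"{L}{name}"), iri(str(RDFS.subClassOf)), iri(f"{L}Thing")))
    return triples


def generate_lotr_bundle(config: FixtureConfig | None = None) -> KGBundle:
    """The guiding fixture (report left empty; run :func:`validate` for it).

    Engineered violations, with the default config:
      * no Hobbit has ``hasAncestry`` and no ``lotr:Hobbit`` object exists
        anywhere → one minimum-count violation per Hobbit;
      * all Hobbits live in TheShire, which is invalid through the cascade;
      * the last ``n_missing_home`` other characters have no home at all, the
        rest point at locations that are invalid through the cascade;
      * every location's region is invalid, because
      * Middle-earth is never typed ``lotr:Continent`` — the single root
        cause that invalidates regions, then locations, then homes.
    """
    config = config or FixtureConfig()
    L = LOTR_NS
    typ = iri(_RDF_TYPE)
    instances: set[Triple] = set()

    hobbits = _names(_HOBBITS, config.n_hobbits, "Hobbit")
    others = _names(_OTHERS, config.n_other_characters, "Character")
    locations = _names(_LOCATIONS, config.n_locations, "Location")
    regions = _names(_REGIONS, config.n_regions, "Region")

    for name in hobbits + others:
        instances.add(Triple(iri(f"{L}{name}"), typ, iri(f"{L}Character")))
    if locations:
        for name in hobbits:
            instances.add(Triple(iri(f"{L}{name}"), iri(f"{L}hasHome"), iri(f"{L}{locations[0]}")))

    used_ancestries: set[str] = set()
    n_homed = config.n_other_characters - config.n_missing_home
    home_pool = locations[1:] if len(locations) > 1 else locations
    for index, name in enumerate(others):
        ancestry = _ANCESTRIES[index % len(_ANCESTRIES)]
        used_ancestries.add(ancestry)
        instances.add(Triple(iri(f"{L}{name}"), iri(f"{L}hasAncestry"), iri(f"{L}{ancestry}")))
        if index < n_homed and home_pool:
            home = home_pool[index % len(home_pool)]
            instances.add(Triple(iri(f"{L}{name}"), iri(f"{L}hasHome"), iri(f"{L}{home}")))

    for ancestry in used_ancestries:
        instances.add(Triple(iri(f"{L}{ancestry}"), typ, iri(f"{L}Ancestry")))

    for location, region in zip(locations, regions):
        instances.add(Triple(iri(f"{L}{location}"), typ, iri(f"{L}Location")))
        instances.add(Triple(iri(f"{L}{location}"), iri(f"{L}isInRegion"), iri(f"{L}{region}")))
    for region in regions:
        instances.add(Triple(iri(f"{L}{region}"), typ, iri(f"{L}Region")))
        instances.add(Triple(iri(f"{L}{region}"), iri(f"{L}isInContinent"), iri(f"{L}MiddleEarth")))
    # Middle-earth exists — but its Continent typing is deliberately absent.
    instances.add(Triple(iri(f"{L}MiddleEarth"), iri(str(RDFS.label)), literal("Middle-earth")))

    return KGBundle(
        ontology=frozenset(_lotr_ontology()),
        instances=frozenset(instances),
        shapes=frozenset(_shape_triples(_lotr_shape_defs(), LOTR_NS)),
        namespaces=_lotr_namespaces(),
    )


def generate_minimal_bundle() -> KGBundle:
    """Two characters, one shape: the smallest bundle with one violation.

    Frodo lacks the required ancestry; Boromir's is properly typed, so only
    Frodo's minimum-count violation is reported.
    """
    L = LOTR_NS
    typ = iri(_RDF_TYPE)
    ontology: set[Triple] = set()
    for name in ("Thing", "Character", "Ancestry"):
        ontology.add(Triple(iri(f"{L}{name}"), typ, iri(str(RDFS.Class))))
        if name != "Thing":
            ontology.add(Triple(iri(f"{L}{name}"), iri(str(RDFS.subClassOf)), iri(f"{L}Thing")))
    instances = {
        Triple(iri(f"{L}Frodo"), typ, iri(f"{L}Character")),
        Triple(iri(f"{L}Boromir"), typ, iri(f"{L}Character")),
        Triple(iri(f"{L}Boromir"), iri(f"{L}hasAncestry"), iri(f"{L}MenOfGondor")),
        Triple(iri(f"{L}MenOfGondor"), typ, iri(f"{L}Ancestry")),
    }
    shape = ShapeDef(
        node_shape=f"{L}CharacterShape",
        target_class=f"{L}Character",
        properties=(
            PropertyDef(
                shape_iri=f"{L}CharacterShape-hasAncestry",
                path=f"{L}hasAncestry",
                min_count=1,
                class_constraint=f"{L}Ancestry",
                message="Character must have an ancestry of class Ancestry.",
            ),
        ),
    )
    return KGBundle(
        ontology=frozenset(ontology),
        instances=frozenset(instances),
        shapes=frozenset(_shape_triples([shape], LOTR_NS)),
        namespaces=_lotr_namespaces(),
    )


# --- mini validator -------------------------------------------------------

def _parse_shape_defs(shapes: Iterable[Triple]) -> list[ShapeDef]:
    idx: dict[Term, dict[str, list[Term]]] = {}
    for t in shapes:
        idx.setdefault(t.subject, {}).setdefault(t.predicate.value, []).append(t.object)

    node_shape_terms = sorted(
        (s for s, po in idx.items() if str(SH.targetClass) in po), key=lambda t: t.value
    )
    property_shape_terms = {
        o for po in idx.values() for o in po.get(str(SH.property), ())
    }

    def first(po: dict[str, list[Term]], pred: str) -> Optional[Term]:
        values = po.get(pred)
        return sorted(values)[0] if values else None

    node_shape_ok = {str(SH.targetClass), str(SH.property), str(SH.message), str(SH.name), _RDF_TYPE}
    defs = []
    for shape_term in node_shape_terms:
        po = idx[shape_term]
        for predicate in sorted(po):
            if predicate.startswith(str(SH)) and predicate not in node_shape_ok:
                raise UnsupportedConstraintError(
                    f"unsupported constraint component <{predicate}> on {shape_term.value}"
                )
        properties = []
        for prop_term in sorted(po.get(str(SH.property), ()), key=lambda t: t.value):
            ppo = idx.get(prop_term, {})
            for predicate in sorted(ppo):
                if predicate.startswith(str(SH)) and predicate not in _SUPPORTED_SHAPE_PREDICATES:
                    raise UnsupportedConstraintError(
                        f"unsupported constraint component <{predicate}> on {prop_term.value}"
                    )
            path = first(ppo, str(SH.path))
            if path is None:
                raise UnsupportedConstraintError(
                    f"property shape {prop_term.value} has no sh:path"
                )
            min_count_term = first(ppo, str(SH.minCount))
            class_term = first(ppo, str(SH["class"]))
            node_term = first(ppo, str(SH.node))
            message_term = first(ppo, str(SH.message))
            properties.append(PropertyDef(
                shape_iri=prop_term.value,
                path=path.value,
                min_count=int(min_count_term.value) if min_count_term else None,
                class_constraint=class_term.value if class_term else None,
                node_constraint=node_term.value if node_term else None,
                message=message_term.value if message_term
                        else f"Violation of {prop_term.value}",
            ))
        defs.append(ShapeDef(
            node_shape=shape_term.value,
            target_class=first(po, str(SH.targetClass)).value,
            properties=tuple(properties),
        ))
    # sanity: property shapes must hang off some node shape we know
    del property_shape_terms
    return defs


def _check_node_acyclic(defs: Sequence[ShapeDef]) -> None:
    by_iri = {d.node_shape: d for d in defs}
    WHITE, GRAY, BLACK = 0, 1, 2
    color = {d.node_shape: WHITE for d in defs}

    def visit(shape: str, stack: list[str]) -> None:
        color[shape] = GRAY
        stack.append(shape)
        for p in by_iri[shape].properties:
            ref = p.node_constraint
            if ref is None or ref not in by_iri:
                continue
            if color[ref] == GRAY:
                cycle = stack[stack.index(ref):] + [ref]
                raise ShapeCycleError(f"sh:node cycle: {' -> '.join(cycle)}")
            if color[ref] == WHITE:
                visit(ref, stack)
        stack.pop()
        color[shape] = BLACK

    for shape in sorted(by_iri):
        if color[shape] == WHITE:
            visit(shape, [])


@dataclass(frozen=True)
class _RawResult:
    focus: Term
    shape: str      # property shape IRI
    path: str
    component: str
    message: str
    value: Optional[Term] = None


def _validate_raw(bundle: KGBundle) -> list[_RawResult]:
    defs = _parse_shape_defs(bundle.shapes)
    _check_node_acyclic(defs)
    by_iri = {d.node_shape: d for d in defs}

    objects: dict[tuple[Term, str], list[Term]] = {}
    types: dict[Term, set[str]] = {}
    for t in bundle.instances:
        objects.setdefault((t.subject, t.predicate.value), []).append(t.object)
        if t.predicate.value == _RDF_TYPE and t.object.kind == "iri":
            types.setdefault(t.subject, set()).add(t.object.value)

    conformance: dict[tuple[Term, str], bool] = {}

    def conforms(node: Term, shape: ShapeDef) -> bool:
        key = (node, shape.node_shape)
        if key in conformance:
            return conformance[key]
        ok = True
        for p in shape.properties:
            values = objects.get((node, p.path), [])
            if p.min_count is not None and len(values) < p.min_count:
                ok = False
                break
            if p.class_constraint is not None and any(
                p.class_constraint not in types.get(v, ()) for v in values
            ):
                ok = False
                break
            if p.node_constraint is not None and p.node_constraint in by_iri and any(
                not conforms(v, by_iri[p.node_constraint]) for v in values
            ):
                ok = False
                break
        conformance[key] = ok
        return ok

    results: list[_RawResult] = []
    for shape in defs:
        targets = sorted(
            (node for node, ts in types.items() if shape.target_class in ts),
            key=lambda t: t.value,
        )
        for node in targets:
            for p in shape.properties:
                values = sorted(objects.get((node, p.path), []))
                if p.min_count is not None and len(values) < p.min_count:
                    results.append(_RawResult(
                        focus=node, shape=p.shape_iri, path=p.path,
                        component=_COMPONENT_MIN_COUNT, message=p.message,
                    ))
                if p.class_constraint is not None:
                    for v in values:
                        if p.class_constraint not in types.get(v, ()):
                            results.append(_RawResult(
                                focus=node, shape=p.shape_iri, path=p.path,
                                component=_COMPONENT_CLASS, message=p.message, value=v,
                            ))
                if p.node_constraint is not None and p.node_constraint in by_iri:
                    inner = by_iri[p.node_constraint]
                    for v in values:
                        if not conforms(v, inner):
                            results.append(_RawResult(
                                focus=node, shape=p.shape_iri, path=p.path,
                                component=_COMPONENT_NODE, message=p.message, value=v,
                            ))
    results.sort(key=lambda r: (r.focus.value, r.shape, r.value.value if r.value else ""))
    return results


def validate(bundle: KGBundle) -> frozenset[Triple]:
    """Validate instances against shapes; returns standard report triples.

    Implements SHACL semantics for targets via ``sh:targetClass`` over
    asserted types and the constraint components ``sh:minCount`` (one
    value-less result when too few values), ``sh:class`` (one result per
    value lacking the asserted type), and ``sh:node`` (one result per value
    not conforming to the referenced shape, checked recursively).  Any other
    SHACL constraint component raises :class:`UnsupportedConstraintError`.
    """
    results = _validate_raw(bundle)
    typ = iri(_RDF_TYPE)
    report_node = blank("report")
    triples: set[Triple] = {
        Triple(report_node, typ, iri(str(SH.ValidationReport))),
        Triple(report_node, iri(str(SH.conforms)),
               literal("true" if not results else "false", datatype=str(XSD.boolean))),
    }
    for index, r in enumerate(results):
        node = blank(f"result{index:04d}")
        triples.add(Triple(report_node, iri(str(SH.result)), node))
        triples.add(Triple(node, typ, iri(str(SH.ValidationResult))))
        triples.add(Triple(node, iri(str(SH.focusNode)), r.focus))
        triples.add(Triple(node, iri(str(SH.resultPath)), iri(r.path)))
        triples.add(Triple(node, iri(str(SH.sourceShape)), iri(r.shape)))
        triples.add(Triple(node, iri(str(SH.sourceConstraintComponent)), iri(r.component)))
        triples.add(Triple(node, iri(str(SH.resultSeverity)), iri(str(SH.Violation))))
        triples.add(Triple(node, iri(str(SH.resultMessage)), literal(r.message)))
        if r.value is not None:
            triples.add(Triple(node, iri(str(SH.value)), r.value))
    return frozenset(triples)


def validated_bundle(bundle: KGBundle) -> KGBundle:
    return bundle.with_report(validate(bundle))


def generate_parametric(
    n_classes: int = 3,
    n_instances_per_class: int = 10,
    violation_rate: float = 0.5,
    cascade_depth: int = 3,
    seed: int = 0,
) -> KGBundle:
    """Parametric cascade bundle for scale and property testing.

    A chain of ``cascade_depth`` classes is linked by ``sh:node`` constraints
    ending in a class constraint on a terminal object; for a
    ``violation_rate`` fraction of the instance chains the terminal object is
    left untyped, so every level of those chains violates — one record per
    level per broken chain.  Extra classes beyond the cascade (when
    ``n_classes`` exceeds ``cascade_depth``) get conforming, untargeted
    instances.  Deterministic per seed.
    """
    if cascade_depth < 1:
        raise FixtureConfigError("cascade_depth must be >= 1")
    if not 0.0 <= violation_rate <= 1.0:
        raise FixtureConfigError("violation_rate must be within [0, 1]")

    S = SYN_NS
    typ = iri(_RDF_TYPE)
    rng = random.Random(seed)

    ontology: set[Triple] = {Triple(iri(f"{S}Root"), typ, iri(str(RDFS.Class)))}
    level_classes = [f"{S}Level{i + 1}" for i in range(cascade_depth)]
    terminal_class = f"{S}Terminal"
    extra_classes = [f"{S}Extra{k + 1}" for k in range(max(0, n_classes - cascade_depth))]
    for c in level_classes + [terminal_class] + extra_classes:
        ontology.add(Triple(iri(c), typ, iri(str(RDFS.Class))))
        ontology.add(Triple(iri(c), iri(str(RDFS.subClassOf)), iri(f"{S}Root")))

    defs = []
    for i, cls in enumerate(level_classes):
        last = i == cascade_depth - 1
        defs.append(ShapeDef(
            node_shape=f"{S}Level{i + 1}Shape",
            target_class=cls,
            properties=(PropertyDef(
                shape_iri=f"{S}Level{i + 1}Shape-next{i + 1}",
                path=f"{S}next{i + 1}",
                min_count=1,
                node_constraint=None if last else f"{S}Level{i + 2}Shape",
                class_constraint=terminal_class if last else None,
                message=f"Level {i + 1} nodes must reference a valid level-{i + 2} node."
                        if not last else
                        f"Level {cascade_depth} nodes must reference a typed terminal.",
            ),),
        ))

    n_broken = round(violation_rate * n_instances_per_class)
    broken = set(rng.sample(range(n_instances_per_class), n_broken))

    instances: set[Triple] = set()
    for j in range(n_instances_per_class):
        chain = [iri(f"{S}n{i + 1}_{j}") for i in range(cascade_depth)]
        terminal = iri(f"{S}t_{j}")
        for i, node in enumerate(chain):
            instances.add(Triple(node, typ, iri(level_classes[i])))
            nxt = chain[i + 1] if i + 1 < cascade_depth else terminal
            instances.add(Triple(node, iri(f"{S}next{i + 1}"), nxt))
        if j not in broken:
            instances.add(Triple(terminal, typ, iri(terminal_class)))
        else:
            instances.add(Triple(terminal, iri(str(RDFS.label)), literal(f"orphan {j}")))
        for cls in extra_classes:
            instances.add(Triple(iri(f"{S}e{cls.rsplit('Extra', 1)[1]}_{j}"), typ, iri(cls)))

    return KGBundle(
        ontology=frozenset(ontology),
        instances=frozenset(instances),
        shapes=frozenset(_shape_triples(defs, SYN_NS)),
        namespaces=NamespaceTable({"syn": SYN_NS, "ex": EX_NS}),
    )
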