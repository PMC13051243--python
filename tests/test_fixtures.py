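from dataclasses import replace

import pytest

from shaclkit.fixtures import (
    LOTR_NS,
    SYN_NS,
    FixtureConfig,
    FixtureConfigError,
    ShapeCycleError,
    UnsupportedConstraintError,
    generate_lotr_bundle,
    generate_minimal_bundle,
    generate_parametric,
    validate,
    validated_bundle,
)
from shaclkit.kg_io import Triple, iri, literal
from shaclkit.report_model import parse_report, records_from_bundle

from .oracles import oracle_validate, record_signature

_TYPE = "http://www.w3.org/1999/02/22-rdf-syntax-ns#type"
_SH = "http://www.w3.org/ns/shacl#"


def _type_census(bundle, class_name):
    return {t.subject.value for t in bundle.instances
            if t.predicate.value == _TYPE and t.object.value == f"{LOTR_NS}{class_name}"}


class TestGuidingFixture:
    def test_default_population_counts(self, lotr_bundle):
        assert len(_type_census(lotr_bundle, "Character")) == 12
        assert len(_type_census(lotr_bundle, "Location")) == 3
        assert len(_type_census(lotr_bundle, "Region")) == 3

    def test_no_hobbit_ancestry_object_exists(self, lotr_bundle):
        assert not any("Hobbit" in t.object.value for t in lotr_bundle.instances
                       if t.predicate.value == f"{LOTR_NS}hasAncestry")

    def test_middle_earth_present_but_untyped(self, lotr_bundle):
        subjects = {t.subject.value for t in lotr_bundle.instances} | \
                   {t.object.value for t in lotr_bundle.instances if t.object.kind == "iri"}
        assert f"{LOTR_NS}MiddleEarth" in subjects
        assert not any(t.subject.value == f"{LOTR_NS}MiddleEarth" and t.predicate.value == _TYPE
                       for t in lotr_bundle.instances)

    def test_validation_yields_23_records(self, lotr_records):
        assert len(lotr_records) == 23

    def test_per_focus_record_counts(self, lotr_records):
        from collections import Counter
        per_focus = Counter(r.focus_node.value for r in lotr_records)
        hobbits = {f"{LOTR_NS}{n}" for n in
                   ("Frodo", "Samwise", "Meriadoc", "Peregrin", "Bilbo")}
        for hobbit in hobbits:
            assert per_focus[hobbit] == 2
        for region in ("Eriador", "Gondor", "Rohan"):
            assert per_focus[f"{LOTR_NS}{region}"] == 1
        for location in ("TheShire", "MinasTirith", "Edoras"):
            assert per_focus[f"{LOTR_NS}{location}"] == 1

    def test_same_config_reproduces_identical_bundle(self):
        a = generate_lotr_bundle(FixtureConfig(seed=3))
        b = generate_lotr_bundle(FixtureConfig(seed=3))
        assert (a.ontology, a.instances, a.shapes) == (b.ontology, b.instances, b.shapes)
        assert validate(a) == validate(b)

    def test_invalid_config_rejected(self):
        with pytest.raises(FixtureConfigError):
            FixtureConfig(n_missing_home=9, n_other_characters=3)
        with pytest.raises(FixtureConfigError):
            FixtureConfig(n_locations=2, n_regions=3)


class TestMinimalFixture:
    def test_single_violation_for_the_ancestry_less_character(self, minimal_bundle):
        records = records_from_bundle(minimal_bundle)
        assert len(records) == 1
        assert records[0].focus_node.value == f"{LOTR_NS}Frodo"

    def test_properly_typed_ancestry_does_not_trigger(self, minimal_bundle):
        records = records_from_bundle(minimal_bundle)
        assert not any(r.focus_node.value == f"{LOTR_NS}Boromir" for r in records)

    def test_repairing_the_missing_ancestry_conforms(self):
        bundle = generate_minimal_bundle()
        repaired = replace(bundle, instances=bundle.instances | {
            Triple(iri(f"{LOTR_NS}Frodo"), iri(f"{LOTR_NS}hasAncestry"), iri(f"{LOTR_NS}Hobbit")),
            Triple(iri(f"{LOTR_NS}Hobbit"), iri(_TYPE), iri(f"{LOTR_NS}Ancestry")),
        })
        assert records_from_bundle(validated_bundle(repaired)) == []


def test_cascade_repair_removes_all_downstream_records():
    """Typing the continent root cause removes region, location, and
    home-invalidity records, leaving only the minimum-count violations."""
    bundle = generate_lotr_bundle()
    repaired = replace(bundle, instances=bundle.instances | {
        Triple(iri(f"{LOTR_NS}MiddleEarth"), iri(_TYPE), iri(f"{LOTR_NS}Continent")),
    })
    records = records_from_bundle(validated_bundle(repaired))
    assert len(records) == 7  # 5 missing ancestries + 2 missing homes
    assert all(r.value is None for r in records)
    assert all(r.constraint_component == f"{_SH}MinCountConstraintComponent" for r in records)


class TestParametric:
    def test_zero_rate_conforms(self):
        bundle = generate_parametric(violation_rate=0.0, seed=1)
        assert records_from_bundle(validated_bundle(bundle)) == []

    def test_full_rate_cascade_hits_every_level(self):
        bundle = generate_parametric(
            n_instances_per_class=10, violation_rate=1.0, cascade_depth=3, seed=2)
        records = records_from_bundle(validated_bundle(bundle))
        assert len(records) == 30  # one record per level per broken chain

    def test_same_seed_identical_record_multisets(self):
        a = validated_bundle(generate_parametric(seed=9))
        b = validated_bundle(generate_parametric(seed=9))
        assert sorted(map(str, records_from_bundle(a))) == sorted(map(str, records_from_bundle(b)))

    def test_depth_one_reduces_to_class_constraint(self):
        bundle = generate_parametric(
            n_instances_per_class=4, violation_rate=1.0, cascade_depth=1, seed=0)
        records = records_from_bundle(validated_bundle(bundle))
        assert len(records) == 4
        assert all(r.value is not None for r in records)

    def test_parameter_validation(self):
        with pytest.raises(FixtureConfigError):
            generate_parametric(cascade_depth=0)
        with pytest.raises(FixtureConfigError):
            generate_parametric(violation_rate=1.5)


class TestValidatorAgainstIndependentOracle:
    """The mini-validator's (focus, shape, value) sets must match an
    independently written rdflib-traversal validator on every fixture."""

    def test_guiding_fixture(self, lotr_bundle, lotr_records, lotr_ns):
        assert record_signature(lotr_records, lotr_ns) == oracle_validate(lotr_bundle)

    def test_minimal_fixture(self, minimal_bundle, lotr_ns):
        records = records_from_bundle(minimal_bundle)
        assert record_signature(records, lotr_ns) == oracle_validate(minimal_bundle)

    @pytest.mark.parametrize("seed", range(5))
    def test_parametric_fixtures(self, seed):
        bundle = validated_bundle(generate_parametric(
            n_instances_per_class=5, violation_rate=0.4, cascade_depth=3, seed=seed))
        records = records_from_bundle(bundle)
        assert record_signature(records, bundle.namespaces) == oracle_validate(bundle)


class TestValidatorErrors:
    def test_unsupported_constraint_component_named(self):
        bundle = generate_minimal_bundle()
        prop = iri(f"{LOTR_NS}CharacterShape-hasAncestry")
        augmented = replace(bundle, shapes=bundle.shapes | {
            Triple(prop, iri(f"{_SH}maxCount"),
                   literal("2", datatype="http://www.w3.org/2001/XMLSchema#integer")),
        })
        with pytest.raises(UnsupportedConstraintError, match="maxCount"):
            validate(augmented)

    def test_node_cycle_detected(self):
        a, b = iri(f"{LOTR_NS}AShape"), iri(f"{LOTR_NS}BShape")
        pa, pb = iri(f"{LOTR_NS}AShape-p"), iri(f"{LOTR_NS}BShape-p")
        typ = iri(_TYPE)
        shapes = frozenset({
            Triple(a, iri(f"{_SH}targetClass"), iri(f"{LOTR_NS}A")),
            Triple(a, iri(f"{_SH}property"), pa),
            Triple(pa, iri(f"{_SH}path"), iri(f"{LOTR_NS}p")),
            Triple(pa, iri(f"{_SH}node"), b),
            Triple(b, iri(f"{_SH}targetClass"), iri(f"{LOTR_NS}B")),
            Triple(b, iri(f"{_SH}property"), pb),
            Triple(pb, iri(f"{_SH}path"), iri(f"{LOTR_NS}q")),
            Triple(pb, iri(f"{_SH}node"), a),
        })
        bundle = replace(generate_minimal_bundle(), shapes=shapes)
        with pytest.raises(ShapeCycleError):
            validate(bundle)


def test_report_envelope_conforms_flag(lotr_bundle):
    conforms = [t for t in lotr_bundle.report if t.predicate.value == f"{_SH}conforms"]
    assert len(conforms) == 1 and conforms[0].object.value == "false"
    clean = generate_parametric(violation_rate=0.0, seed=0)
    report = validate(clean)
    conforms = [t for t in report if t.predicate.value == f"{_SH}conforms"]
    assert len(conforms) == 1 and conforms[0].object.value == "true"
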