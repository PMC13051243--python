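import pytest
from hypothesis import settings

from shaclkit import (
    build_feature_matrix,
    build_focus_table,
    embed_2d,
    generate_lotr_bundle,
    generate_minimal_bundle,
    group_violations,
    records_from_bundle,
    validated_bundle,
)

settings.register_profile("default", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("default")


@pytest.fixture(scope="session")
def lotr_bundle():
    """The guiding fixture, validated: 23 records over 18 focus nodes."""
    return validated_bundle(generate_lotr_bundle())


@pytest.fixture(scope="session")
def lotr_records(lotr_bundle):
    return records_from_bundle(lotr_bundle)


@pytest.fixture(scope="session")
def lotr_ns(lotr_bundle):
    return lotr_bundle.namespaces


@pytest.fixture(scope="session")
def lotr_groups(lotr_records, lotr_ns):
    return group_violations(lotr_records, lotr_ns)


@pytest.fixture(scope="session")
def lotr_table(lotr_bundle, lotr_records):
    return build_focus_table(lotr_bundle, lotr_records)


@pytest.fixture(scope="session")
def lotr_embedding(lotr_table):
    """Shared seeded UMAP embedding of the violations feature matrix."""
    matrix = build_feature_matrix(lotr_table, "violations")
    return embed_2d(matrix, seed=42)


@pytest.fixture(scope="session")
def minimal_bundle():
    return validated_bundle(generate_minimal_bundle())
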