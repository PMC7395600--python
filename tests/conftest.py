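import pytest
from hypothesis import settings

from taxoswitch import Checklist, Role, TaxonRecord, parse_scientific_name
from taxoswitch.fixtures import celastrina_fixture, expected_celastrina_matrix

settings.register_profile("ci", derandomize=True, max_examples=100)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def celastrina():
    return celastrina_fixture()


@pytest.fixture(scope="session")
def expected_matrix():
    return expected_celastrina_matrix()


def make_checklist(names, source="list", role=Role.PROGRAM, base_id=None):
    """Build an in-memory checklist from plain name strings."""
    records = [
        TaxonRecord(
            taxon_id="%s-%03d" % (source, i),
            parent_id=None,
            name=parse_scientific_name(n),
            source=source,
        )
        for i, n in enumerate(names)
    ]
    return Checklist(source, role, records, base_id=base_id)


@pytest.fixture
def checklist_factory():
    return make_checklist
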