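import pytest

from varqa.identifiers import TableRecoder
from varqa.synthetic_data import (
    CANONICAL_RS,
    DEFAULT_RS_IDS,
    StubLlm,
    canonical_record_json,
    write_fixture_dir,
)
from varqa.variant_store import MockVariantClient


@pytest.fixture(scope="session")
def canonical_json() -> str:
    return canonical_record_json()


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    return write_fixture_dir(tmp_path_factory.mktemp("variants"), DEFAULT_RS_IDS, seed=0)


@pytest.fixture()
def mock_client(fixture_dir) -> MockVariantClient:
    return MockVariantClient(fixture_dir)


@pytest.fixture(scope="session")
def recoder() -> TableRecoder:
    return TableRecoder(
        {"ENST00000298910.12:c.6055G>A": "12:40340400:G:A"}
    )


@pytest.fixture(scope="session")
def empty_recoder() -> TableRecoder:
    return TableRecoder({})


@pytest.fixture(scope="session")
def stub_llm() -> StubLlm:
    return StubLlm()


@pytest.fixture(scope="session")
def canonical_rs() -> str:
    return CANONICAL_RS
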