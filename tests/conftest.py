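import pytest

from ontosearch import AnnotationStore, OntoSearch, fixture
from ontosearch.synthetic import FIXTURE_NAMES


@pytest.fixture(params=FIXTURE_NAMES)
def any_fixture(request):
    """(name, ontology, instances) for each named worked-example fixture."""
    onto, instances = fixture(request.param)
    return request.param, onto, instances


def build_engine(name: str) -> OntoSearch:
    onto, instances = fixture(name)
    return OntoSearch(onto, AnnotationStore(onto, instances))


@pytest.fixture
def rodents():
    return build_engine("rodent_strains")


@pytest.fixture
def hippocampus():
    return build_engine("hippocampus_layers")


@pytest.fixture
def insula():
    return build_engine("fronto_insula")


@pytest.fixture
def purkinje():
    return build_engine("purkinje_hook")


@pytest.fixture
def granule():
    return build_engine("granule_homonym")


@pytest.fixture
def cuticle():
    return build_engine("class_iii_cuticle")
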