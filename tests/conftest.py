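import numpy as np
import pytest

from hdmp.disease_similarity import DiseaseSimilarityConfig
from hdmp.fixtures import paper_fixture
from hdmp.ontology import build_disease_dag, contribution_map


@pytest.fixture(scope="session")
def paper():
    return paper_fixture()


@pytest.fixture(scope="session")
def layer_config():
    return DiseaseSimilarityConfig(scheme="layer", delta=0.5)


@pytest.fixture(scope="session")
def ln_dag(paper):
    return build_disease_dag(paper.ontology, paper.liver_neoplasms)


@pytest.fixture(scope="session")
def pn_dag(paper):
    return build_disease_dag(paper.ontology, paper.pancreatic_neoplasms)


@pytest.fixture(scope="session")
def bn_dag(paper):
    return build_disease_dag(paper.ontology, paper.breast_neoplasms)


@pytest.fixture
def rng():
    return np.random.default_rng(20130808)
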