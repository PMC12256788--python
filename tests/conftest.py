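import numpy as np
import pytest

from mitotriage.io import load_fixture_ontology
from mitotriage.ontology import Ontology, PhenotypeProfile, compute_ic


@pytest.fixture(scope="session")
def fixture_ont():
    return load_fixture_ontology()


@pytest.fixture()
def diamond_ont():
    """Four-term diamond: R <- A, R <- B, A <- C, B <- C."""
    return Ontology.from_edges({"R": [], "A": ["R"], "B": ["R"],
                                "C": ["A", "B"]})


@pytest.fixture()
def diamond_ic(diamond_ont):
    """Corpus chosen so IC(R)=0, IC(A)=IC(B)=ln 2, IC(C)=ln 4."""
    corpus = [PhenotypeProfile("p1", {"C"}), PhenotypeProfile("p2", {"A"}),
              PhenotypeProfile("p3", {"B"}), PhenotypeProfile("p4", {"R"})]
    return compute_ic(diamond_ont, corpus)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
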