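import numpy as np
import pytest

from ppigo.network import AnnotationMap, InteractionNetwork
from ppigo.ontology import Ontology, OntologyTerm
from ppigo.scoring import FunctionInfluence
from ppigo.synthdata import toy_ontology

T1, T2, T3, T4, T5 = (f"GO:{i:07d}" for i in range(1, 6))

TOY_OBO = """\
format-version: 1.2
ontology: toy

[Term]
id: GO:0000001
name: term one
namespace: biological_process

[Term]
id: GO:0000002
name: term two
namespace: biological_process

[Term]
id: GO:0000003
name: term three
namespace: biological_process

[Term]
id: GO:0000004
name: term four
namespace: biological_process
is_a: GO:0000002 ! term two
is_a: GO:0000003 ! term three

[Term]
id: GO:0000005
name: term five
namespace: biological_process
is_a: GO:0000003 ! term three
is_a: GO:0000004 ! term four
"""


@pytest.fixture(scope="session")
def toy_onto() -> Ontology:
    return toy_ontology()


@pytest.fixture()
def toy_obo_path(tmp_path):
    path = tmp_path / "toy.obo"
    path.write_text(TOY_OBO)
    return path


@pytest.fixture()
def toy_instance(toy_onto):
    """Three proteins on the five-term DAG: target P with neighbours
    P1 (term four) and P2 (term five)."""
    net = InteractionNetwork.from_edges([("P", "P1"), ("P", "P2")])
    ann = AnnotationMap({"P1": {T4}, "P2": {T5}})
    influence = FunctionInfluence(
        total_proteins=3, per_term_count={T4: 1, T5: 1}
    )
    return net, ann, influence


def make_ontology(parents_of: dict[str, set[str]]) -> Ontology:
    return Ontology(
        [OntologyTerm(id=t, parents=frozenset(ps))
         for t, ps in parents_of.items()]
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(20111110)
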