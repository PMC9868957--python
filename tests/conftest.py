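import numpy as np
import pytest

from germscore.ontology import Ontology, _build
from germscore.synth import SyntheticConfig, gen_ontology


CHAIN_OBO = """format-version: 1.2

[Term]
id: T:A
name: root term

[Term]
id: T:B
name: middle term
is_a: T:A

[Term]
id: T:C
name: leaf term
is_a: T:B
"""


@pytest.fixture
def chain_obo(tmp_path):
    p = tmp_path / "chain.obo"
    p.write_text(CHAIN_OBO)
    return p


@pytest.fixture
def chain_ontology() -> Ontology:
    return _build(["T:A", "T:B", "T:C"], [("T:B", "T:A"), ("T:C", "T:B")])


@pytest.fixture
def glioma_like_ontology() -> tuple[Ontology, str]:
    """Root with a neoplasm branch and a nervous-system branch; the
    glioma-like term descends from both."""
    terms = ["HP:root", "HP:neoplasm", "HP:nervous", "HP:glioma",
             "HP:seizure"]
    edges = [("HP:neoplasm", "HP:root"), ("HP:nervous", "HP:root"),
             ("HP:glioma", "HP:neoplasm"), ("HP:glioma", "HP:nervous"),
             ("HP:seizure", "HP:nervous")]
    return _build(terms, edges), "HP:neoplasm"


def random_dag(seed: int, n_terms: int = 60) -> Ontology:
    ontology, _ = gen_ontology(SyntheticConfig(n_terms=n_terms, seed=seed))
    return ontology


@pytest.fixture
def small_config() -> SyntheticConfig:
    return SyntheticConfig(n_genes=400, n_terms=40, n_tumor_types=8,
                           n_diseases=40, phenotypes_per_disease=3, seed=11)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
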