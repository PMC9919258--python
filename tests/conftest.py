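import numpy as np
import pytest

from kgddi import synthkg
from kgddi.featurize import FingerprintSet
from kgddi.kg_store import Entity, Relation, Triple, build_kg


@pytest.fixture()
def toy_kg():
    """5 entities, 2 relations, a drug connected to protein/gene/disease context."""
    entities = [
        Entity(0, "drugA", "drug"),
        Entity(1, "drugB", "drug"),
        Entity(2, "prot1", "protein"),
        Entity(3, "gene1", "gene"),
        Entity(4, "dis1", "disease"),
    ]
    relations = [Relation(0, "targets"), Relation(1, "assoc")]
    triples = [
        Triple(0, 0, 2),
        Triple(1, 0, 2),
        Triple(0, 1, 3),
        Triple(3, 1, 4),
        Triple(1, 1, 4),
    ]
    return build_kg(entities, relations, triples)


@pytest.fixture()
def tiny_fps():
    return FingerprintSet(4, {0: [1, 0, 0, 1], 1: [0, 1, 0, 1], 2: [1, 1, 0, 0]})


@pytest.fixture(scope="session")
def small_world():
    """A small but fully wired synthetic world shared across tests."""
    cfg = synthkg.SynthConfig(
        n_drugs=60, n_proteins=30, n_genes=20, n_diseases=15, n_pairs=400, seed=1
    )
    return synthkg.generate(cfg)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
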