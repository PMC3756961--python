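import numpy as np
import pytest

from entcite.corpus import Corpus, Document
from entcite.lexicon import EntityId, EntityType, build_lexicon
from entcite.network import EntityCitationNetwork


def eid(type_char: str, ident: str, name: str | None = None) -> EntityId:
    etype = {"G": EntityType.GENE, "D": EntityType.DRUG, "Z": EntityType.DISEASE}[type_char]
    return EntityId(etype, ident, name)


@pytest.fixture
def small_lexicon():
    """Drug/gene/disease mini-dictionary with an overlapping surface pair."""
    return build_lexicon(
        [
            ("Metformin", eid("D", "DB00331", "metformin")),
            ("Glucophage", eid("D", "DB00331", "metformin")),
            ("Insulin", eid("G", "P01308", "insulin")),
            ("insulin resistance", eid("Z", "D007333", "insulin resistance")),
            ("Obesity", eid("Z", "D009765", "obesity")),
            ("ACTA1", eid("G", "P68133", "acta1")),
            ("actin, alpha 1, skeletal muscle", eid("G", "P68133", "acta1")),
        ]
    )


@pytest.fixture
def small_corpus():
    """Three citing docs and two cited-only docs; x0 is unresolvable."""
    return Corpus(
        [
            Document("a", "Metformin and obesity", "insulin resistance improves.",
                     ["d", "e", "x0"]),
            Document("b", "Insulin signalling", "A study of insulin and obesity.", ["d"]),
            Document("c", "Unrelated title", "Nothing relevant here.", ["e"]),
            Document("d", "Insulin basics", "Insulin.", []),
            Document("e", "Obesity review", "Obesity and metformin.", []),
        ]
    )


def random_entity_digraph(seed: int, n_max: int = 9, p: float | None = None):
    """Random directed loopful graph over typed entity nodes."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(2, n_max + 1))
    if p is None:
        p = float(rng.uniform(0.15, 0.6))
    chars = ["G", "D", "Z"]
    nodes = [eid(chars[i % 3], f"N{i:02d}") for i in range(n)]
    weights = {}
    for a in nodes:
        for b in nodes:
            if rng.random() < p:
                weights[(a, b)] = int(rng.integers(1, 5))
    isolated = {v for v in nodes if not any(v in arc for arc in weights)}
    return EntityCitationNetwork(weights, isolated)


def undirected_edges(net: EntityCitationNetwork):
    """Edge list of the underlying undirected simple graph."""
    return {frozenset((a, b)) for a, b in net.weights if a != b}


def as_pairs(edges):
    return [tuple(e) for e in edges]
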