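"""Synthetic lexicons and annotated citation corpora with known ground truth.

The generator emulates the structure of a query-selected biomedical citation
corpus: documents appear in temporal order and cite only earlier documents
(uniformly or by linear preferential attachment with the classic
Barabasi-Albert kernel, probability proportional to mean-out-degree plus
current in-degree, whose in-degree tail has exponent near 3);
titles and abstracts are synthetic word salad with typed entity surface forms
embedded at token boundaries, entity choice following a Zipf law so frequency
tables show realistic skew.  Optionally a focal entity's interaction partners
are *planted*: documents mentioning the focal entity cite the partners' seed
documents with citation weight boosted by a factor beta, which elevates the
partners' in-degree in the projected entity network — a recoverable analog of
a drug's curated interaction profile.

Everything is deterministic given the config seed: one numpy Generator drives
all randomness, and every emitted file is byte-identical across runs.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .corpus import Corpus, Document
from .lexicon import EntityId, EntityType, Lexicon, build_lexicon

# filler vocabulary for synthetic prose; never overlaps generated surfaces
_FILLER = (
    "study results suggest role of the in with for patients analysis model "
    "data effect treatment observed increased decreased levels expression "
    "response clinical between association significant cohort baseline"
).split()

_CONSONANTS = "bcdfgklmnprstvz"
_VOWELS = "aeiou"


@dataclass(frozen=True)
class PlantedSpec:
    """Planted focal-entity interaction structure.

    ``beta`` multiplies the citation weight of partner seed documents when the
    citing document mentions the focal entity; ``beta = 1`` is the null (no
    signal).  ``seed_docs_per_partner`` early documents mention each partner
    exclusively, so that partner in-degree is attributable to the planted
    citations.  When ``focal`` / ``partners`` are left unset the generator
    picks the most popular drug as focal and the least popular
    ``n_partners`` entities of ``partner_type`` as partners.
    """

    beta: float = 20.0
    n_partners: int = 5
    partner_type: EntityType = EntityType.GENE
    focal: EntityId | None = None
    partners: tuple[EntityId, ...] | None = None
    seed_docs_per_partner: int = 3
    # the citing corpus models a query-selected collection centred on the
    # focal entity, so most documents mention it
    focal_doc_fraction: float = 0.8

    def __post_init__(self) -> None:
        if self.beta < 1:
            raise ValueError("beta must be >= 1")
        if self.n_partners < 1:
            raise ValueError("n_partners must be >= 1")


@dataclass
class SynthConfig:
    """Study conditions for one synthetic corpus.

    Defaults describe a small query-selected collection: 500 documents, a
    lexicon of 50 genes / 25 drugs / 25 diseases with 1-3 synonyms each,
    5 references and 4 entity mentions per document on average, preferential
    attachment citations, and Zipf(s=1.0) entity popularity.
    """

    n_docs: int = 500
    n_entities: dict[EntityType, int] = field(
        default_factory=lambda: {
            EntityType.GENE: 50,
            EntityType.DRUG: 25,
            EntityType.DISEASE: 25,
        }
    )
    refs_per_doc: float = 5.0
    attachment: str = "preferential"
    mentions_per_doc: float = 4.0
    zipf_s: float = 1.0
    planted: PlantedSpec | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_docs < 1:
            raise ValueError("n_docs must be >= 1")
        if any(v < 1 for v in self.n_entities.values()):
            raise ValueError("entity counts must be positive")
        if self.attachment not in ("uniform", "preferential"):
            raise ValueError(f"unknown attachment {self.attachment!r}")
        if self.zipf_s < 0:
            raise ValueError("zipf_s must be >= 0")


@dataclass
class GroundTruth:
    """What the generator actually planted, for end-to-end oracles."""

    mentions: dict[str, Counter]  # doc_id -> Counter[EntityId]
    arcs: set[tuple[str, str]]
    focal: EntityId | None = None
    partners: tuple[EntityId, ...] = ()
    clipped_refs: int = 0
    popularity_order: list[EntityId] = field(default_factory=list)

    def to_json(self) -> dict:
        return {
            "mentions": {
                doc: {e.key: c for e, c in sorted(cnt.items(), key=lambda kv: kv[0].key)}
                for doc, cnt in sorted(self.mentions.items())
            },
            "arcs": sorted(list(a) for a in self.arcs),
            "focal": self.focal.key if self.focal else None,
            "partners": [p.key for p in self.partners],
            "clipped_refs": self.clipped_refs,
        }


def _word(rng: np.random.Generator, n_syllables: int) -> str:
    return "".join(
        _CONSONANTS[rng.integers(len(_CONSONANTS))] + _VOWELS[rng.integers(len(_VOWELS))]
        for _ in range(n_syllables)
    )


def generate_lexicon(config: SynthConfig) -> Lexicon:
    """Random typed lexicon: unique base word per entity plus 0-2 synonyms
    (one derived single-token alias and one derived two-word alias), all
    surfaces unique across entities.  Deterministic given ``config.seed``."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    reserved: set[str] = set(_FILLER)
    mappings: list[tuple[str, EntityId]] = []
    prefix = {EntityType.GENE: "G", EntityType.DRUG: "R", EntityType.DISEASE: "Z"}
    for etype in (EntityType.GENE, EntityType.DRUG, EntityType.DISEASE):
        for i in range(config.n_entities[etype]):
            while True:
                base = _word(rng, 3)
                derived = {base, base + "ex1", base + "extra"}
                if not (derived & reserved):
                    reserved |= derived
                    break
            entity = EntityId(etype, f"{prefix[etype]}{i:04d}", base)
            mappings.append((base, entity))
            n_syn = int(rng.integers(0, 3))  # 0, 1 or 2 extra synonyms
            if n_syn >= 1:
                mappings.append((base + "ex1", entity))
            if n_syn >= 2:
                mappings.append((f"{base} {base}extra", entity))
    return build_lexicon(mappings)


def _popularity(lex: Lexicon, rng: np.random.Generator, s: float) -> tuple[list[EntityId], np.ndarray]:
    """Deterministic random popularity order and Zipf(s) weights."""
    entities = sorted(lex.entities(), key=lambda e: (e.entity_type.value, e.canonical_id))
    order = [entities[i] for i in rng.permutation(len(entities))]
    weights = np.array([(r + 1.0) ** -s for r in range(len(order))])
    return order, weights / weights.sum()


def generate_corpus(
    config: SynthConfig, lex: Lexicon | None = None
) -> tuple[Corpus, GroundTruth, Lexicon]:
    """Generate a corpus honoring :class:`SynthConfig`; returns the corpus,
    the planted ground truth, and the lexicon used.

    Planted focal interactions (when ``config.planted`` is set): the first
    ``n_partners * seed_docs_per_partner`` documents each mention exactly one
    partner; later documents mention the focal entity with probability
    ``focal_doc_fraction``, and those focal documents choose their references
    with partner seed documents up-weighted by ``beta``.
    """
    if lex is None:
        lex = generate_lexicon(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 202]))
    order, weights = _popularity(lex, rng, config.zipf_s)
    surfaces_of: dict[EntityId, list[str]] = {}
    for surface, entity in lex:
        surfaces_of.setdefault(entity, []).append(surface)
    for lst in surfaces_of.values():
        lst.sort()

    planted = config.planted
    focal: EntityId | None = None
    partners: tuple[EntityId, ...] = ()
    partner_seed_docs: dict[int, EntityId] = {}
    if planted is not None:
        if planted.focal is not None:
            focal = planted.focal
        else:  # most popular drug
            focal = next(e for e in order if e.entity_type == EntityType.DRUG)
        if planted.partners is not None:
            partners = planted.partners
        else:  # least popular entities of the partner type
            pool = [e for e in reversed(order) if e.entity_type == planted.partner_type]
            partners = tuple(pool[: planted.n_partners])
        if len(partners) < planted.n_partners:
            raise ValueError("not enough entities of partner_type to plant")
        # seed documents are spread over the early-to-middle corpus rather
        # than placed at the head: under preferential attachment the very
        # first documents accumulate citations regardless of any boost
        # (first-mover advantage), which would fake a signal at beta = 1
        n_seed = len(partners) * planted.seed_docs_per_partner
        lo = int(0.05 * config.n_docs)
        # widen past 0.15n only when a small corpus cannot hold all seeds
        hi = max(int(0.15 * config.n_docs), lo + n_seed)
        if hi >= config.n_docs:
            raise ValueError("n_docs too small for the planted seed documents")
        positions = [lo + round(j * (hi - lo - 1) / max(1, n_seed - 1)) for j in range(n_seed)]
        for j, pos in enumerate(positions):
            partner_seed_docs[pos] = partners[j % len(partners)]

    docs: list[Document] = []
    truth_mentions: dict[str, Counter] = {}
    arcs: set[tuple[str, str]] = set()
    in_degree = np.zeros(config.n_docs)
    clipped = 0

    def sample_entities(k: int) -> list[EntityId]:
        idxs = rng.choice(len(order), size=k, p=weights)
        return [order[i] for i in idxs]

    def render(mention_entities: list[EntityId]) -> tuple[str, str, Counter]:
        title = " ".join(rng.choice(_FILLER, size=4))
        parts: list[str] = []
        counts: Counter = Counter()
        for e in mention_entities:
            parts.extend(rng.choice(_FILLER, size=int(rng.integers(1, 4))))
            surface = surfaces_of[e][int(rng.integers(len(surfaces_of[e])))]
            parts.append(surface)
            counts[e] += 1
        parts.extend(rng.choice(_FILLER, size=2))
        return title, " ".join(parts) + ".", counts

    for i in range(config.n_docs):
        doc_id = f"d{i:05d}"
        is_focal_doc = False
        if i in partner_seed_docs:
            mention_entities = [partner_seed_docs[i]]
        else:
            n_mentions = max(1, int(rng.poisson(config.mentions_per_doc)))
            mention_entities = sample_entities(n_mentions)
            if planted is not None and rng.random() < planted.focal_doc_fraction:
                assert focal is not None
                mention_entities.append(focal)
                is_focal_doc = True
        title, abstract, counts = render(mention_entities)

        n_refs = int(rng.poisson(config.refs_per_doc))
        if n_refs > i:
            clipped += n_refs - i
            n_refs = i
        refs: list[str] = []
        if n_refs > 0:
            if config.attachment == "preferential":
                # Barabasi-Albert kernel: offset by the mean out-degree so the
                # in-degree tail has the classic exponent near 3
                w = config.refs_per_doc + in_degree[:i]
            else:
                w = np.ones(i)
            if is_focal_doc and planted is not None:
                for j in partner_seed_docs:
                    if j < i:
                        w[j] *= planted.beta
            p = w / w.sum()
            chosen = rng.choice(i, size=n_refs, replace=False, p=p)
            for j in sorted(int(c) for c in chosen):
                refs.append(f"d{j:05d}")
                in_degree[j] += 1
                arcs.add((doc_id, f"d{j:05d}"))

        docs.append(Document(doc_id, title, abstract, refs, year=2000 + i * 10 // config.n_docs))
        truth_mentions[doc_id] = counts

    truth = GroundTruth(truth_mentions, arcs, focal, partners, clipped, list(order))
    return Corpus(docs), truth, lex


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(truth.to_json(), fh, indent=2, sort_keys=True)
        fh.write("\n")
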