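"""Exact dictionary chunking of titles and abstracts (the EntityFetcher stage).

Matching is exact on normalized text under the longest-leftmost rule: at each
position the longest lexicon surface that starts there (at a token boundary,
ending at a token boundary) wins, the scan resumes after it, and shorter
overlapping surfaces are suppressed.  This is the standard contract of exact
dictionary chunkers and is fully deterministic.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd

from .corpus import Corpus, PaperCitationGraph
from .lexicon import EntityId, Lexicon, normalize_surface

# separator between title and abstract; never part of any normalized surface,
# so no match can span the boundary
DOC_TEXT_SEPARATOR = "\n"


@dataclass(frozen=True)
class EntityMention:
    """One chunk: ``surface`` equals the normalized text slice
    ``text[char_start:char_end]``."""

    doc_id: str
    entity: EntityId
    surface: str
    char_start: int
    char_end: int

    def __post_init__(self) -> None:
        if not (0 <= self.char_start < self.char_end):
            raise ValueError("require 0 <= char_start < char_end")


def _is_token_char(ch: str) -> bool:
    return ch.isalnum()


class _SurfaceIndex:
    """Surfaces grouped by first character, longest first."""

    def __init__(self, lex: Lexicon):
        by_first: dict[str, list[str]] = {}
        for surface, _ in lex:
            by_first.setdefault(surface[0], []).append(surface)
        for lst in by_first.values():
            lst.sort(key=len, reverse=True)
        self.by_first = by_first
        self.lex = lex


def chunk_text(text: str, lex: Lexicon, doc_id: str = "") -> list[EntityMention]:
    """All non-overlapping longest-leftmost matches of the lexicon in ``text``.

    ``text`` is normalized with the lexicon's policy before matching; offsets
    refer to the normalized string.  Matches must start and end at token
    boundaries (never inside an alphanumeric run).
    """
    if len(lex) == 0:
        raise ValueError("lexicon is empty")
    # normalize per line so matches never span a newline (the title/abstract
    # separator); offsets refer to the normalized lines re-joined by "\n"
    segments = [normalize_surface(seg, lex.policy) for seg in text.split(DOC_TEXT_SEPARATOR)]
    index = _SurfaceIndex(lex)
    mentions: list[EntityMention] = []
    base = 0
    for seg in segments:
        mentions.extend(_chunk_segment(seg, index, doc_id, base))
        base += len(seg) + 1
    return mentions


def _chunk_segment(
    norm: str, index: _SurfaceIndex, doc_id: str, base: int
) -> list[EntityMention]:
    mentions: list[EntityMention] = []
    i, n = 0, len(norm)
    while i < n:
        # only start at a token boundary
        if i > 0 and _is_token_char(norm[i - 1]) and _is_token_char(norm[i]):
            i += 1
            continue
        matched = False
        for surface in index.by_first.get(norm[i], ()):
            end = i + len(surface)
            if end > n or norm[i:end] != surface:
                continue
            if end < n and _is_token_char(norm[end - 1]) and _is_token_char(norm[end]):
                continue  # ends inside an alphanumeric run
            mentions.append(
                EntityMention(
                    doc_id, index.lex.entries[surface], surface, base + i, base + end
                )
            )
            i = end
            matched = True
            break
        if not matched:
            i += 1
    return mentions


class AnnotationMap:
    """Per-document multiset of recognized entities (mention counts)."""

    def __init__(self) -> None:
        self._counts: dict[str, Counter] = {}
        self._mentions: dict[str, list[EntityMention]] = {}

    def record(self, doc_id: str, mentions: list[EntityMention]) -> None:
        self._mentions[doc_id] = mentions
        self._counts[doc_id] = Counter(m.entity for m in mentions)

    def counts(self, doc_id: str) -> Counter:
        """Mention multiset of one document (empty Counter when unannotated)."""
        return Counter(self._counts.get(doc_id, Counter()))

    def entity_set(self, doc_id: str) -> frozenset[EntityId]:
        return frozenset(self._counts.get(doc_id, ()))

    def mentions(self, doc_id: str) -> list[EntityMention]:
        return list(self._mentions.get(doc_id, []))

    @property
    def doc_ids(self) -> set[str]:
        return set(self._counts)

    def __len__(self) -> int:
        return len(self._counts)

    def all_entities(self) -> set[EntityId]:
        out: set[EntityId] = set()
        for c in self._counts.values():
            out.update(c)
        return out

    def per_type_totals(self) -> dict[str, int]:
        """Distinct entities per type over all annotated documents."""
        totals = Counter(e.entity_type.value for e in self.all_entities())
        return dict(totals)


def doc_text(title: str, abstract: str, lex: Lexicon) -> str:
    """Normalized matching text of a document: title and abstract joined by a
    separator that blocks cross-boundary matches."""
    return (
        normalize_surface(title, lex.policy)
        + DOC_TEXT_SEPARATOR
        + normalize_surface(abstract, lex.policy)
    )


def annotate_corpus(corpus: Corpus, lex: Lexicon, doc_ids: Iterable[str]) -> AnnotationMap:
    """Run :func:`chunk_text` over the title+abstract of each listed document."""
    ids = set(doc_ids)
    missing = ids - corpus.ids
    if missing:
        raise KeyError(f"doc ids not in corpus: {sorted(missing)[:5]}")
    ann = AnnotationMap()
    for doc_id in sorted(ids):
        doc = corpus[doc_id]
        text = doc_text(doc.title, doc.abstract, lex)
        ann.record(doc_id, chunk_text(text, lex, doc_id))
    return ann


_TABLE_COLUMNS = ["rank", "entity_type", "entity_id", "entity_name", "count"]


def _ranked_table(counts: dict[EntityId, int]) -> pd.DataFrame:
    rows = sorted(
        counts.items(),
        key=lambda kv: (-kv[1], kv[0].entity_type.value, kv[0].canonical_id),
    )
    return pd.DataFrame(
        [
            {
                "rank": i,
                "entity_type": e.entity_type.value,
                "entity_id": e.canonical_id,
                "entity_name": e.preferred_name or e.canonical_id,
                "count": c,
            }
            for i, (e, c) in enumerate(rows, start=1)
        ],
        columns=_TABLE_COLUMNS,
    )


def citing_frequency_table(
    ann: AnnotationMap,
    citing_ids: Iterable[str],
    *,
    mode: str = "documents",
) -> pd.DataFrame:
    """Ranked entity frequencies over the citing set.

    ``mode="documents"`` (default) counts the number of citing documents that
    mention the entity; ``mode="mentions"`` counts total mentions.
    """
    if mode not in ("documents", "mentions"):
        raise ValueError(f"unknown mode {mode!r}")
    counts: Counter = Counter()
    for doc_id in citing_ids:
        c = ann.counts(doc_id)
        if mode == "documents":
            counts.update(set(c))
        else:
            counts.update(c)
    return _ranked_table(counts)


def cited_citation_table(
    ann: AnnotationMap,
    pg: PaperCitationGraph,
    *,
    mode: str = "arcs",
) -> pd.DataFrame:
    """Ranked citation counts of entities in the cited set.

    ``mode="arcs"`` (default) counts citation events: the number of arcs
    (citing, cited) whose cited document mentions the entity.
    ``mode="papers"`` counts distinct cited documents mentioning the entity.
    """
    if mode not in ("arcs", "papers"):
        raise ValueError(f"unknown mode {mode!r}")
    counts: Counter = Counter()
    if mode == "arcs":
        for _, cited in pg.arcs:
            counts.update(ann.entity_set(cited))
    else:
        for cited in pg.cited_ids:
            counts.update(ann.entity_set(cited))
    return _ranked_table(counts)


def write_annotations(ann: AnnotationMap, path: str | Path) -> None:
    """TSV export: doc_id, entity_type, canonical_id, surface, start, end."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("doc_id\tentity_type\tcanonical_id\tsurface\tstart\tend\n")
        for doc_id in sorted(ann.doc_ids):
            for m in ann.mentions(doc_id):
                fh.write(
                    f"{m.doc_id}\t{m.entity.entity_type.value}\t{m.entity.canonical_id}"
                    f"\t{m.surface}\t{m.char_start}\t{m.char_end}\n"
                )
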