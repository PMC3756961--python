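"""Document corpora and the paper-level citation graph.

A corpus is a set of document records (id, title, abstract, reference-id
list) stored as JSON Lines.  The citing set is selected by query terms
matched at token boundaries on normalized title/abstract text, emulating a
title/abstract keyword search; the paper citation graph keeps only arcs whose
cited endpoint resolves inside the corpus (mirroring a PMID-only filter) and
reports how many references were dropped.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from .lexicon import DEFAULT_POLICY, NormalizationPolicy, normalize_surface


class CorpusError(Exception):
    pass


class CorpusParseError(CorpusError):
    def __init__(self, message: str, line_no: int | None = None):
        self.line_no = line_no
        if line_no is not None:
            message = f"line {line_no}: {message}"
        super().__init__(message)


class CorpusIntegrityError(CorpusError):
    pass


@dataclass
class Document:
    doc_id: str
    title: str = ""
    abstract: str = ""
    references: list[str] = field(default_factory=list)
    year: int | None = None

    def __post_init__(self) -> None:
        if not self.doc_id:
            raise CorpusIntegrityError("doc_id must be non-empty")
        # duplicate reference entries collapse on ingestion (first occurrence
        # order preserved)
        self.references = list(dict.fromkeys(self.references))


class Corpus:
    """Mapping ``doc_id -> Document``."""

    def __init__(self, documents: Iterable[Document] = ()):
        self._docs: dict[str, Document] = {}
        for doc in documents:
            self.add(doc)

    def add(self, doc: Document) -> None:
        if doc.doc_id in self._docs:
            raise CorpusIntegrityError(f"duplicate doc_id {doc.doc_id!r}")
        self._docs[doc.doc_id] = doc

    def __len__(self) -> int:
        return len(self._docs)

    def __contains__(self, doc_id: str) -> bool:
        return doc_id in self._docs

    def __getitem__(self, doc_id: str) -> Document:
        return self._docs[doc_id]

    def __iter__(self) -> Iterator[Document]:
        return iter(self._docs.values())

    def get(self, doc_id: str) -> Document | None:
        return self._docs.get(doc_id)

    @property
    def ids(self) -> set[str]:
        return set(self._docs)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Corpus):
            return NotImplemented
        return self._docs == other._docs


def read_corpus(path: str | Path) -> Corpus:
    """Read a JSON Lines corpus: one object per line with keys
    ``doc_id``, ``title``, ``abstract``, ``references`` and optional ``year``.
    """
    corpus = Corpus()
    with open(path, encoding="utf-8") as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise CorpusParseError(f"malformed JSON: {exc}", line_no) from None
            if not isinstance(rec, dict) or "doc_id" not in rec:
                raise CorpusParseError("record must be an object with a doc_id", line_no)
            doc = Document(
                doc_id=str(rec["doc_id"]),
                title=rec.get("title", ""),
                abstract=rec.get("abstract", ""),
                references=[str(r) for r in rec.get("references", [])],
                year=rec.get("year"),
            )
            try:
                corpus.add(doc)
            except CorpusIntegrityError as exc:
                raise CorpusIntegrityError(f"line {line_no}: {exc}") from None
    return corpus


def write_corpus(corpus: Corpus, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for doc in corpus:
            rec = {
                "doc_id": doc.doc_id,
                "title": doc.title,
                "abstract": doc.abstract,
                "references": doc.references,
            }
            if doc.year is not None:
                rec["year"] = doc.year
            fh.write(json.dumps(rec, ensure_ascii=False) + "\n")


@dataclass
class QuerySpec:
    """Term list searched on normalized title/abstract at token boundaries."""

    terms: list[str]
    fields_searched: frozenset[str] = frozenset({"title", "abstract"})
    year_range: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if not self.terms:
            raise ValueError("QuerySpec.terms must be non-empty")
        bad = set(self.fields_searched) - {"title", "abstract"}
        if bad:
            raise ValueError(f"unknown searchable fields: {sorted(bad)}")


def _term_pattern(term: str) -> re.Pattern:
    # whole-token-boundary containment: the match may not begin or end inside
    # an alphanumeric run
    return re.compile(rf"(?<![0-9a-z]){re.escape(term)}(?![0-9a-z])")


def filter_citing_set(
    corpus: Corpus,
    query: QuerySpec,
    *,
    policy: NormalizationPolicy = DEFAULT_POLICY,
) -> set[str]:
    """Select the citing set: ids of documents containing at least one query
    term (token-boundary substring of the normalized searched fields), within
    the year range when one is given."""
    patterns = [_term_pattern(normalize_surface(t, policy)) for t in query.terms]
    hits: set[str] = set()
    for doc in corpus:
        if query.year_range is not None:
            lo, hi = query.year_range
            if doc.year is None or not (lo <= doc.year <= hi):
                continue
        parts = []
        if "title" in query.fields_searched:
            parts.append(normalize_surface(doc.title, policy))
        if "abstract" in query.fields_searched:
            parts.append(normalize_surface(doc.abstract, policy))
        text = "\n".join(parts)
        if any(p.search(text) for p in patterns):
            hits.add(doc.doc_id)
    return hits


@dataclass
class PaperCitationGraph:
    """Arcs (citing doc, cited doc) restricted to resolvable cited ids."""

    citing_ids: frozenset[str]
    arcs: frozenset[tuple[str, str]]
    dropped_references: int = 0

    @property
    def cited_ids(self) -> frozenset[str]:
        return frozenset(b for _, b in self.arcs)

    @property
    def n_arcs(self) -> int:
        return len(self.arcs)


def build_paper_citation_graph(corpus: Corpus, citing_ids: Iterable[str]) -> PaperCitationGraph:
    """Build the paper citation graph over a citing set.

    References pointing outside the corpus (the analog of references without
    a resolvable identifier) are dropped and counted.
    """
    citing = frozenset(citing_ids)
    missing = citing - corpus.ids
    if missing:
        raise CorpusIntegrityError(f"citing ids not in corpus: {sorted(missing)[:5]}")
    arcs: set[tuple[str, str]] = set()
    dropped = 0
    for cid in citing:
        for ref in corpus[cid].references:
            if ref in corpus:
                arcs.add((cid, ref))
            else:
                dropped += 1
    return PaperCitationGraph(citing, frozenset(arcs), dropped)


def write_paper_graph(pg: PaperCitationGraph, path: str | Path) -> None:
    """Two-column TSV export (citing_id, cited_id)."""
    with open(path, "w", encoding="utf-8") as fh:
        for a, b in sorted(pg.arcs):
            fh.write(f"{a}\t{b}\n")
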