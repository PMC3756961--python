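"""Typed bio-entity lexicon: surface forms mapped to canonical gene/drug/disease IDs.

The lexicon is a flat dictionary of normalized surface forms (names, synonyms,
aliases) pointing to a canonical entity, encoded on disk one mapping per line
as ``surface<TAB>TYPE__ID`` (canonical TSV dialect) or ``surface –>TYPE__ID``
(legacy arrow dialect, read-only).  All synonyms of one entity resolve to the
same ``(type, id)`` pair, which is what lets exact-match chunking recognize an
entity under any of its names.
"""

from __future__ import annotations

import enum
import re
import unicodedata
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator


class EntityType(enum.Enum):
    """The three entity classes recognized by the pipeline."""

    GENE = "GENE"
    DRUG = "DRUG"
    DISEASE = "DISEASE"

    def __lt__(self, other: "EntityType") -> bool:
        if not isinstance(other, EntityType):
            return NotImplemented
        return self.value < other.value


@dataclass(frozen=True, order=True)
class EntityId:
    """Canonical identity of one entity: ``(entity_type, canonical_id)``.

    ``preferred_name`` is a display label (the first surface form seen for the
    entity); it is carried for reporting but excluded from equality, so two
    references to the same canonical entity compare equal regardless of which
    synonym introduced them.
    """

    entity_type: EntityType
    canonical_id: str
    preferred_name: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not self.canonical_id:
            raise ValueError("canonical_id must be non-empty")

    @property
    def label(self) -> str:
        """Human-readable ``TYPE_name`` label (table style)."""
        return f"{self.entity_type.value}_{self.preferred_name or self.canonical_id}"

    @property
    def key(self) -> str:
        """Parseable ``TYPE__ID`` encoding (file style)."""
        return f"{self.entity_type.value}__{self.canonical_id}"

    @classmethod
    def from_key(cls, key: str, preferred_name: str | None = None) -> "EntityId":
        type_part, sep, id_part = key.partition("__")
        if not sep or not id_part:
            raise ValueError(f"not a TYPE__ID token: {key!r}")
        try:
            etype = EntityType(type_part)
        except ValueError:
            raise ValueError(f"unknown entity type prefix {type_part!r} in {key!r}") from None
        return cls(etype, id_part, preferred_name)


class LexiconError(Exception):
    """Base class for lexicon loading problems."""


class LexiconParseError(LexiconError):
    def __init__(self, message: str, line_no: int | None = None):
        self.line_no = line_no
        if line_no is not None:
            message = f"line {line_no}: {message}"
        super().__init__(message)


class LexiconConflictError(LexiconError):
    """One surface form mapped to two different entities."""


_WS_RUN = re.compile(r"\s+")
# punctuation stripped only at the edges; internal punctuation is meaningful
# ("actin, alpha 1" stays intact)
_EDGE_PUNCT = re.compile(r"^[^\w]+|[^\w]+$", re.UNICODE)


@dataclass(frozen=True)
class NormalizationPolicy:
    """How surface forms and document text are canonicalized before matching.

    Matching is exact on the normalized strings, so the policy is shared by
    the lexicon, the chunker, the query filter, and the evaluation matcher.
    """

    casefold: bool = True
    collapse_whitespace: bool = True
    strip_edge_punctuation: bool = True

    def apply(self, text: str) -> str:
        out = unicodedata.normalize("NFKC", text)
        if self.casefold:
            out = out.lower()
        if self.collapse_whitespace:
            out = _WS_RUN.sub(" ", out).strip()
        if self.strip_edge_punctuation:
            out = _EDGE_PUNCT.sub("", out)
        return out


DEFAULT_POLICY = NormalizationPolicy()


def normalize_surface(text: str, policy: NormalizationPolicy = DEFAULT_POLICY) -> str:
    """Normalize a surface form or free text span.  Idempotent."""
    return policy.apply(text)


class Lexicon:
    """Map from normalized surface form to :class:`EntityId`.

    Invariant: every surface maps to exactly one entity; all synonyms of one
    entity share the same ``(type, id)``.
    """

    def __init__(self, policy: NormalizationPolicy = DEFAULT_POLICY):
        self.policy = policy
        self._entries: dict[str, EntityId] = {}
        # first surface registered per entity, kept as its preferred name
        self._preferred: dict[tuple[EntityType, str], str] = {}

    def add(self, surface: str, entity: EntityId, *, on_conflict: str = "error") -> None:
        norm = normalize_surface(surface, self.policy)
        if not norm:
            raise LexiconError(f"surface {surface!r} is empty after normalization")
        existing = self._entries.get(norm)
        if existing is not None and (
            existing.entity_type != entity.entity_type
            or existing.canonical_id != entity.canonical_id
        ):
            if on_conflict == "first-wins":
                return
            raise LexiconConflictError(
                f"surface {norm!r} maps to both {existing.key} and {entity.key}"
            )
        pref_key = (entity.entity_type, entity.canonical_id)
        preferred = self._preferred.setdefault(pref_key, entity.preferred_name or norm)
        self._entries[norm] = EntityId(entity.entity_type, entity.canonical_id, preferred)

    def get(self, surface: str) -> EntityId | None:
        return self._entries.get(normalize_surface(surface, self.policy))

    def __contains__(self, surface: str) -> bool:
        return self.get(surface) is not None

    def __len__(self) -> int:
        return len(self._entries)

    def __iter__(self) -> Iterator[tuple[str, EntityId]]:
        return iter(self._entries.items())

    @property
    def entries(self) -> dict[str, EntityId]:
        return dict(self._entries)

    @property
    def surface_count(self) -> int:
        return len(self._entries)

    def entities(self) -> set[EntityId]:
        return set(self._entries.values())

    def surfaces_of(self, entity: EntityId) -> set[str]:
        return {s for s, e in self._entries.items() if e == entity}

    def synonyms(self, name: str) -> set[str]:
        """All surfaces resolving to the same entity as ``name`` (incl. itself)."""
        entity = self.get(name)
        if entity is None:
            return set()
        return self.surfaces_of(entity)


_ARROW_SEPS = ("–>", "→", "->")  # "–>", "→", ASCII fallback


def _split_line(line: str, dialect: str) -> tuple[str, str] | None:
    if dialect in ("tsv", "auto") and "\t" in line:
        surface, _, key = line.partition("\t")
        return surface, key.strip()
    if dialect in ("arrow", "auto"):
        for sep in _ARROW_SEPS:
            if sep in line:
                surface, _, key = line.partition(sep)
                return surface, key.strip()
    return None


def load_lexicon(
    path: str | Path,
    dialect: str = "auto",
    *,
    policy: NormalizationPolicy = DEFAULT_POLICY,
    on_conflict: str = "error",
) -> Lexicon:
    """Load a lexicon file.

    Parameters
    ----------
    path:
        UTF-8 text file, one ``surface SEPARATOR TYPE__ID`` mapping per line.
        ``#``-prefixed lines and blank lines are ignored.
    dialect:
        ``"tsv"`` (tab separator), ``"arrow"`` (``–>`` / ``->``), or
        ``"auto"`` to accept either per line.
    on_conflict:
        ``"error"`` (default) raises :class:`LexiconConflictError` when one
        surface maps to two entities; ``"first-wins"`` keeps the first mapping.
    """
    if dialect not in ("auto", "tsv", "arrow"):
        raise ValueError(f"unknown dialect {dialect!r}")
    lex = Lexicon(policy)
    with open(path, encoding="utf-8") as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = _split_line(line, dialect)
            if parts is None:
                raise LexiconParseError(f"no separator found in {line!r}", line_no)
            surface, key = parts
            if not surface.strip():
                raise LexiconParseError(f"empty surface in {line!r}", line_no)
            try:
                entity = EntityId.from_key(key)
            except ValueError as exc:
                raise LexiconParseError(str(exc), line_no) from None
            try:
                lex.add(surface, entity, on_conflict=on_conflict)
            except LexiconConflictError as exc:
                raise LexiconConflictError(f"line {line_no}: {exc}") from None
    return lex


def write_lexicon(lex: Lexicon, path: str | Path) -> None:
    """Write the canonical TSV dialect: ``surface<TAB>TYPE__ID``, sorted."""
    with open(path, "w", encoding="utf-8") as fh:
        for surface in sorted(lex.entries):
            fh.write(f"{surface}\t{lex.entries[surface].key}\n")


def lexicon_stats(lex: Lexicon) -> dict:
    """Per-type surface and entity counts plus totals."""
    surfaces = {t: 0 for t in EntityType}
    entities: dict[EntityType, set[str]] = {t: set() for t in EntityType}
    for _, entity in lex:
        surfaces[entity.entity_type] += 1
        entities[entity.entity_type].add(entity.canonical_id)
    return {
        "surfaces": {t.value: surfaces[t] for t in EntityType},
        "entities": {t.value: len(entities[t]) for t in EntityType},
        "total_surfaces": sum(surfaces.values()),
        "total_entities": sum(len(v) for v in entities.values()),
    }


def build_lexicon(
    mappings: Iterable[tuple[str, EntityId]],
    *,
    policy: NormalizationPolicy = DEFAULT_POLICY,
    on_conflict: str = "error",
) -> Lexicon:
    """Build a lexicon in memory from ``(surface, entity)`` pairs."""
    lex = Lexicon(policy)
    for surface, entity in mappings:
        lex.add(surface, entity, on_conflict=on_conflict)
    return lex
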