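"""Evaluation of top-ranked entities against a curated interaction reference.

The reference is a TSV export of curated partner records for one focal entity
(a drug, typically), each carrying a curation rank and/or an association
score.  Matching is by normalized name (optionally widened with lexicon
synonyms), never by ID, since curated vocabularies and the extraction lexicon
rarely share identifiers.  Matched reference ranks are then summarized over
rank bands (by default top-10 / 11-100 / beyond).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .lexicon import (
    DEFAULT_POLICY,
    EntityId,
    EntityType,
    Lexicon,
    NormalizationPolicy,
    normalize_surface,
)

logger = logging.getLogger(__name__)


class EvaluationError(Exception):
    pass


@dataclass(frozen=True)
class ReferenceRecord:
    name: str
    partner_type: EntityType
    rank: int | None = None
    score: float | None = None
    annotation: str = ""

    def __post_init__(self) -> None:
        if self.rank is None and self.score is None:
            raise EvaluationError(f"record {self.name!r} has neither rank nor score")
        if self.rank is not None and self.rank < 1:
            raise EvaluationError(f"record {self.name!r} has non-positive rank")


class ReferenceSet:
    """Curated partner records indexed by (type, normalized name)."""

    def __init__(self, policy: NormalizationPolicy = DEFAULT_POLICY):
        self.policy = policy
        self._records: dict[tuple[EntityType, str], ReferenceRecord] = {}

    def add(self, record: ReferenceRecord) -> None:
        key = (record.partner_type, normalize_surface(record.name, self.policy))
        existing = self._records.get(key)
        if existing is not None:
            # keep the best (lowest) rank; unranked never displaces ranked
            keep_new = (
                existing.rank is None
                or (record.rank is not None and record.rank < existing.rank)
            )
            logger.warning(
                "duplicate reference name %r (%s): keeping rank %s",
                record.name,
                record.partner_type.value,
                (record if keep_new else existing).rank,
            )
            if not keep_new:
                return
        self._records[key] = record

    def lookup(self, name: str, partner_type: EntityType) -> ReferenceRecord | None:
        return self._records.get((partner_type, normalize_surface(name, self.policy)))

    def __len__(self) -> int:
        return len(self._records)

    @property
    def records(self) -> list[ReferenceRecord]:
        return list(self._records.values())

    def count_of_type(self, partner_type: EntityType) -> int:
        return sum(1 for t, _ in self._records if t == partner_type)


_REQUIRED_COLUMNS = {"partner_name", "partner_type"}


def load_reference(
    path: str | Path, *, policy: NormalizationPolicy = DEFAULT_POLICY
) -> ReferenceSet:
    """Read the reference TSV: header columns partner_name, partner_type,
    rank, score, annotation (rank or score may be empty, not both)."""
    ref = ReferenceSet(policy)
    with open(path, encoding="utf-8") as fh:
        header_line = fh.readline().rstrip("\n")
        columns = header_line.split("\t")
        missing = _REQUIRED_COLUMNS - set(columns)
        if missing:
            raise EvaluationError(f"reference file missing columns: {sorted(missing)}")
        idx = {c: i for i, c in enumerate(columns)}
        for line_no, raw in enumerate(fh, start=2):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")

            def get(col: str) -> str:
                i = idx.get(col)
                return parts[i].strip() if i is not None and i < len(parts) else ""

            try:
                ptype = EntityType(get("partner_type").upper())
            except ValueError:
                raise EvaluationError(
                    f"line {line_no}: unknown partner_type {get('partner_type')!r}"
                ) from None
            rank_s, score_s = get("rank"), get("score")
            try:
                record = ReferenceRecord(
                    name=get("partner_name"),
                    partner_type=ptype,
                    rank=int(rank_s) if rank_s else None,
                    score=float(score_s) if score_s else None,
                    annotation=get("annotation"),
                )
            except (ValueError, EvaluationError) as exc:
                raise EvaluationError(f"line {line_no}: {exc}") from None
            ref.add(record)
    return ref


@dataclass
class MatchReport:
    measure: str
    entity_type: EntityType
    top_k: list[EntityId]
    matched: list[tuple[EntityId, ReferenceRecord]] = field(default_factory=list)
    unmatched: list[EntityId] = field(default_factory=list)

    @property
    def n_matched(self) -> int:
        return len(self.matched)

    def matched_ranks(self) -> list[int]:
        return [rec.rank for _, rec in self.matched if rec.rank is not None]

    def to_dict(self) -> dict:
        return {
            "measure": self.measure,
            "entity_type": self.entity_type.value,
            "k": len(self.top_k),
            "n_matched": self.n_matched,
            "matched": [
                {"entity": e.label, "reference_rank": rec.rank, "score": rec.score}
                for e, rec in self.matched
            ],
            "unmatched": [e.label for e in self.unmatched],
        }


def match_top_k(
    top_k: Sequence[EntityId],
    ref: ReferenceSet,
    *,
    measure: str = "",
    lexicon: Lexicon | None = None,
    stoplist: Iterable[str] | None = None,
) -> MatchReport:
    """Match a ranked per-type entity list against the reference by name.

    An entity matches when its normalized preferred name, or any of its
    lexicon synonyms, equals a reference record name of the same type.
    ``stoplist`` names (generic terms) are excluded from matching entirely.
    """
    if not top_k:
        raise EvaluationError("top_k list is empty")
    types = {e.entity_type for e in top_k}
    if len(types) != 1:
        raise EvaluationError("top_k list mixes entity types")
    etype = types.pop()
    stop = {normalize_surface(s, ref.policy) for s in (stoplist or ())}
    report = MatchReport(measure, etype, list(top_k))
    for e in top_k:
        names = {normalize_surface(e.preferred_name or e.canonical_id, ref.policy)}
        if lexicon is not None:
            names |= lexicon.surfaces_of(e)
        names -= stop
        hit = None
        for name in sorted(names):
            hit = ref.lookup(name, etype)
            if hit is not None:
                break
        if hit is not None:
            report.matched.append((e, hit))
        else:
            report.unmatched.append(e)
    return report


DEFAULT_BANDS: tuple[tuple[int, float], ...] = ((1, 10), (11, 100), (101, math.inf))


def rank_bands(
    report: MatchReport,
    bands: Sequence[tuple[int, float]] = DEFAULT_BANDS,
) -> dict[str, int]:
    """Counts of matched reference ranks per band.

    Bands must be disjoint and cover [1, inf).  Matches without a rank are
    reported under ``"unranked"``.
    """
    expected_lo = 1
    for lo, hi in bands:
        if lo != expected_lo or hi < lo:
            raise EvaluationError(f"bands must be disjoint and cover [1, inf): {bands}")
        expected_lo = int(hi) + 1 if math.isfinite(hi) else None
        if expected_lo is None:
            break
    if expected_lo is not None:
        raise EvaluationError(f"bands do not cover [1, inf): {bands}")

    def band_name(lo: int, hi: float) -> str:
        return f"{lo}-{int(hi)}" if math.isfinite(hi) else f"{lo}+"

    counts = {band_name(lo, hi): 0 for lo, hi in bands}
    unranked = 0
    for _, rec in report.matched:
        if rec.rank is None:
            unranked += 1
            continue
        for lo, hi in bands:
            if lo <= rec.rank <= hi:
                counts[band_name(lo, hi)] += 1
                break
    if unranked:
        counts["unranked"] = unranked
    return counts


def write_report(report: MatchReport, band_counts: dict[str, int], path: str | Path) -> None:
    payload = report.to_dict()
    payload["band_counts"] = band_counts
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")


def load_stoplist(path: str | Path) -> list[str]:
    """Plain-text stoplist, one generic term per line; blanks/# ignored."""
    out = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            term = line.strip()
            if term and not term.startswith("#"):
                out.append(term)
    return out
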