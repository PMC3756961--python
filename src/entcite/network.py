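"""The weighted directed entity-entity citation network (GraphCreator stage).

For every paper arc A -> B, each entity mentioned in A is paired with each
entity mentioned in B; each such ordered pair increments the weight of the
entity arc by one.  Pairing uses each document's entity *set* by default, so
one paper citation contributes at most 1 to a given entity pair; a
mention-multiplicity mode weights pairs by the product of mention counts.
Self-citations (the same entity on both sides) become loops.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import networkx as nx

from .corpus import PaperCitationGraph
from .lexicon import EntityId
from .ner import AnnotationMap


class NetworkError(Exception):
    pass


class NetworkParseError(NetworkError):
    def __init__(self, message: str, line_no: int | None = None):
        if line_no is not None:
            message = f"line {line_no}: {message}"
        super().__init__(message)


def _sort_key(e: EntityId) -> tuple[str, str]:
    return (e.entity_type.value, e.canonical_id)


@dataclass
class EntityCitationNetwork:
    """Weighted digraph over typed entities; loops allowed, weights >= 1."""

    weights: dict[tuple[EntityId, EntityId], int] = field(default_factory=dict)
    isolated: set[EntityId] = field(default_factory=set)

    def __post_init__(self) -> None:
        for arc, w in self.weights.items():
            if w < 1:
                raise NetworkError(f"arc {arc[0].key}->{arc[1].key} has weight {w} < 1")

    @property
    def nodes(self) -> set[EntityId]:
        out = set(self.isolated)
        for a, b in self.weights:
            out.add(a)
            out.add(b)
        return out

    @property
    def n(self) -> int:
        return len(self.nodes)

    @property
    def m(self) -> int:
        """Number of distinct weighted arcs (loops included)."""
        return len(self.weights)

    @property
    def loop_count(self) -> int:
        return sum(1 for a, b in self.weights if a == b)

    @property
    def total_weight(self) -> int:
        return sum(self.weights.values())

    def weight(self, source: EntityId, target: EntityId) -> int:
        return self.weights.get((source, target), 0)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, EntityCitationNetwork):
            return NotImplemented
        return self.weights == other.weights and self.nodes == other.nodes

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        for node in self.nodes:
            g.add_node(node)
        for (a, b), w in self.weights.items():
            g.add_edge(a, b, weight=w)
        return g


def build_entity_network(
    pg: PaperCitationGraph,
    ann: AnnotationMap,
    *,
    use_mention_multiplicity: bool = False,
) -> EntityCitationNetwork:
    """Project the paper citation graph onto entities.

    For each arc (A, B) and each ordered entity pair (ea, eb) with ea
    mentioned in A and eb in B, weight(ea -> eb) grows by 1 (or by the product
    of mention counts when ``use_mention_multiplicity`` is set).  The result
    is independent of arc iteration order.
    """
    weights: dict[tuple[EntityId, EntityId], int] = defaultdict(int)
    for citing, cited in pg.arcs:
        if use_mention_multiplicity:
            src = ann.counts(citing)
            dst = ann.counts(cited)
            for ea, ca in src.items():
                for eb, cb in dst.items():
                    weights[(ea, eb)] += ca * cb
        else:
            for ea in ann.entity_set(citing):
                for eb in ann.entity_set(cited):
                    weights[(ea, eb)] += 1
    return EntityCitationNetwork(dict(weights))


# --- serialization -----------------------------------------------------------

_FORMATS = ("tsv", "pajek", "graphml")


def write_network(net: EntityCitationNetwork, path: str | Path, format: str = "tsv") -> None:
    """Lossless export in ``tsv``, ``pajek`` or ``graphml``.

    TSV columns: source_type, source_id, target_type, target_id, weight.
    Pajek uses 1-based vertex numbering with parseable ``TYPE__ID`` labels.
    """
    if format not in _FORMATS:
        raise NetworkError(f"unknown format {format!r}; expected one of {_FORMATS}")
    path = Path(path)
    if format == "tsv":
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("source_type\tsource_id\ttarget_type\ttarget_id\tweight\n")
            for (a, b), w in sorted(
                net.weights.items(), key=lambda kv: (_sort_key(kv[0][0]), _sort_key(kv[0][1]))
            ):
                fh.write(
                    f"{a.entity_type.value}\t{a.canonical_id}"
                    f"\t{b.entity_type.value}\t{b.canonical_id}\t{w}\n"
                )
    elif format == "pajek":
        order = sorted(net.nodes, key=_sort_key)
        index = {e: i for i, e in enumerate(order, start=1)}
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"*Vertices {len(order)}\n")
            for e in order:
                fh.write(f'{index[e]} "{e.key}"\n')
            fh.write("*Arcs\n")
            for (a, b), w in sorted(
                net.weights.items(), key=lambda kv: (index[kv[0][0]], index[kv[0][1]])
            ):
                fh.write(f"{index[a]} {index[b]} {w}\n")
    else:  # graphml
        g = nx.DiGraph()
        for e in sorted(net.nodes, key=_sort_key):
            g.add_node(
                e.key,
                entity_type=e.entity_type.value,
                canonical_id=e.canonical_id,
                name=e.preferred_name or "",
            )
        for (a, b), w in net.weights.items():
            g.add_edge(a.key, b.key, weight=int(w))
        nx.write_graphml(g, path)


def read_network(path: str | Path, format: str = "tsv") -> EntityCitationNetwork:
    """Inverse of :func:`write_network` for all three formats."""
    if format not in _FORMATS:
        raise NetworkError(f"unknown format {format!r}; expected one of {_FORMATS}")
    path = Path(path)
    if format == "tsv":
        return _read_tsv(path)
    if format == "pajek":
        return _read_pajek(path)
    g = nx.read_graphml(path)
    weights: dict[tuple[EntityId, EntityId], int] = {}
    nodes = {key: EntityId.from_key(key) for key in g.nodes}
    for a, b, data in g.edges(data=True):
        w = int(data.get("weight", 1))
        if w < 1:
            raise NetworkParseError(f"arc {a}->{b} has non-positive weight {w}")
        weights[(nodes[a], nodes[b])] = w
    isolated = {e for key, e in nodes.items() if g.degree(key) == 0}
    return EntityCitationNetwork(weights, isolated)


def _read_tsv(path: Path) -> EntityCitationNetwork:
    weights: dict[tuple[EntityId, EntityId], int] = {}
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
        if header and not header.startswith("source_type"):
            raise NetworkParseError("missing TSV header", 1)
        for line_no, raw in enumerate(fh, start=2):
            line = raw.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 5:
                raise NetworkParseError(f"expected 5 columns, got {len(parts)}", line_no)
            st, sid, tt, tid, w_str = parts
            try:
                a = EntityId.from_key(f"{st}__{sid}")
                b = EntityId.from_key(f"{tt}__{tid}")
                w = int(w_str)
            except ValueError as exc:
                raise NetworkParseError(str(exc), line_no) from None
            if w < 1:
                raise NetworkParseError(f"non-positive weight {w}", line_no)
            weights[(a, b)] = w
    return EntityCitationNetwork(weights)


def _read_pajek(path: Path) -> EntityCitationNetwork:
    vertices: dict[int, EntityId] = {}
    weights: dict[tuple[EntityId, EntityId], int] = {}
    section = None
    with open(path, encoding="utf-8") as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            low = line.lower()
            if low.startswith("*vertices"):
                section = "vertices"
                continue
            if low.startswith("*arcs"):
                section = "arcs"
                continue
            if line.startswith("*"):
                raise NetworkParseError(f"unsupported section {line!r}", line_no)
            if section == "vertices":
                idx_str, _, rest = line.partition(" ")
                label = rest.strip().strip('"')
                try:
                    vertices[int(idx_str)] = EntityId.from_key(label)
                except ValueError as exc:
                    raise NetworkParseError(str(exc), line_no) from None
            elif section == "arcs":
                parts = line.split()
                if len(parts) != 3:
                    raise NetworkParseError(f"expected 'src dst w', got {line!r}", line_no)
                try:
                    a, b, w = int(parts[0]), int(parts[1]), int(parts[2])
                except ValueError:
                    raise NetworkParseError(f"non-integer arc line {line!r}", line_no) from None
                if w < 1:
                    raise NetworkParseError(f"non-positive weight {w}", line_no)
                if a not in vertices or b not in vertices:
                    raise NetworkParseError(f"arc references unknown vertex in {line!r}", line_no)
                weights[(vertices[a], vertices[b])] = w
            else:
                raise NetworkParseError(f"content before any section: {line!r}", line_no)
    used = {e for arc in weights for e in arc}
    isolated = set(vertices.values()) - used
    return EntityCitationNetwork(weights, isolated)
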