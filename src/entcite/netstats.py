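"""Macro-, meso-, and micro-level statistics of the entity citation network.

Two views of the network are used deliberately:

* the *directed, loopful* view for degrees, degree histograms, and density
  (density = m / n^2, so the complete digraph with loops has density 1);
* the *underlying undirected, unweighted, loop-free simple graph* for all
  cohesion and distance measures (components, bi-components, k-core, geodesic
  distances, clustering, closeness, betweenness), since reachability claims
  about citation networks refer to semi-paths.

Arc weights are ignored by every statistic here; they are projection counts,
not distances.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable

import networkx as nx
import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import zeta

from .lexicon import EntityId, EntityType
from .network import EntityCitationNetwork


class StatsError(Exception):
    pass


def _key(e: EntityId) -> tuple[str, str]:
    return (e.entity_type.value, e.canonical_id)


def undirected_simple(net: EntityCitationNetwork) -> nx.Graph:
    """Underlying undirected simple graph: direction, weights, loops dropped."""
    g = nx.Graph()
    g.add_nodes_from(net.nodes)
    for a, b in net.weights:
        if a != b:
            g.add_edge(a, b)
    return g


def density(net: EntityCitationNetwork) -> float:
    """Directed density with loops allowed: m / n^2."""
    if net.n == 0:
        raise StatsError("density undefined for an empty network")
    return net.m / net.n**2


def weak_components(net: EntityCitationNetwork) -> list[set[EntityId]]:
    """Connected components of the underlying undirected graph, largest first."""
    comps = [set(c) for c in nx.connected_components(undirected_simple(net))]
    comps.sort(key=lambda c: (-len(c), min(_key(e) for e in c)))
    return comps


def bicomponents(net: EntityCitationNetwork) -> list[set[EntityId]]:
    """Biconnected components of the underlying simple graph.

    Articulation points belong to several components; single edges form
    2-node components; isolated nodes belong to none.
    """
    comps = [set(c) for c in nx.biconnected_components(undirected_simple(net))]
    comps.sort(key=lambda c: (-len(c), min(_key(e) for e in c)))
    return comps


@dataclass
class CoreDecomposition:
    core_number: dict[EntityId, int]
    max_core_k: int
    max_core_members: set[EntityId]


def kcore(net: EntityCitationNetwork) -> CoreDecomposition:
    """Core decomposition by iterative pruning on the undirected simple graph."""
    g = undirected_simple(net)
    if g.number_of_nodes() == 0:
        return CoreDecomposition({}, 0, set())
    core = nx.core_number(g)
    max_k = max(core.values())
    members = {v for v, k in core.items() if k == max_k}
    return CoreDecomposition(dict(core), max_k, members)


@dataclass
class DistanceStats:
    mean_distance: float
    diameter: int
    diameter_pair: tuple[EntityId, EntityId]
    n_nodes_used: int
    restricted_to_largest_component: bool


def distance_stats(net: EntityCitationNetwork) -> DistanceStats:
    """Mean geodesic distance and diameter on the undirected simple graph.

    d-bar = (1 / N(N-1)) * sum over ordered pairs i != j of d_ij.  When the
    graph is disconnected the largest component is used and flagged.  The
    diameter-achieving pair returned is the lexicographically smallest one.
    """
    g = undirected_simple(net)
    if g.number_of_nodes() < 2:
        raise StatsError("distance statistics need at least 2 nodes")
    restricted = False
    if not nx.is_connected(g):
        comps = weak_components(net)
        g = g.subgraph(comps[0]).copy()
        restricted = True
        if g.number_of_nodes() < 2:
            raise StatsError("largest component has fewer than 2 nodes")
    nodes = sorted(g.nodes, key=_key)
    total = 0
    diam = 0
    pair: tuple[EntityId, EntityId] | None = None
    for u in nodes:
        lengths = nx.single_source_shortest_path_length(g, u)
        for v in nodes:
            if v is u:
                continue
            d = lengths[v]
            total += d
            if d > diam or (
                d == diam
                and pair is not None
                and (_key(u), _key(v)) < (_key(pair[0]), _key(pair[1]))
            ):
                diam = d
                pair = (u, v)
            elif pair is None:
                diam = d
                pair = (u, v)
    n = len(nodes)
    assert pair is not None
    return DistanceStats(total / (n * (n - 1)), diam, pair, n, restricted)


def degree_distributions(net: EntityCitationNetwork) -> tuple[dict[int, int], dict[int, int]]:
    """(in-degree histogram, out-degree histogram) on the directed loopful
    view; a loop contributes 1 to both degrees of its node."""
    indeg: Counter = Counter()
    outdeg: Counter = Counter()
    for node in net.nodes:
        indeg[node] = 0
        outdeg[node] = 0
    for a, b in net.weights:
        outdeg[a] += 1
        indeg[b] += 1
    return dict(Counter(indeg.values())), dict(Counter(outdeg.values()))


@dataclass
class PowerLawFit:
    gamma: float
    xmin: int
    n_tail: int
    log_likelihood: float
    lsq_slope: float


def fit_power_law(histogram: dict[int, int], xmin: int = 1) -> PowerLawFit:
    """Discrete maximum-likelihood power-law exponent of a degree histogram.

    Maximizes the zeta-normalized likelihood P(k) = k^-gamma / zeta(gamma,
    xmin) over k >= xmin.  A log-log least-squares slope over the same support
    is returned as a diagnostic.  Requires at least 3 distinct positive degree
    values at or above ``xmin``.
    """
    tail = {k: c for k, c in histogram.items() if k >= xmin and k > 0 and c > 0}
    if len(tail) < 3:
        raise StatsError(
            f"power-law fit needs >= 3 distinct positive degrees >= xmin={xmin}, got {len(tail)}"
        )
    ks = np.array(sorted(tail), dtype=float)
    cs = np.array([tail[int(k)] for k in ks], dtype=float)
    n = cs.sum()
    sum_log_k = float((cs * np.log(ks)).sum())

    def neg_loglik(g: float) -> float:
        return g * sum_log_k + n * math.log(zeta(g, xmin))

    res = minimize_scalar(neg_loglik, bounds=(1.0001, 12.0), method="bounded")
    slope = float(np.polyfit(np.log(ks), np.log(cs), 1)[0])
    return PowerLawFit(float(res.x), xmin, int(n), -float(res.fun), slope)


def global_clustering(net: EntityCitationNetwork) -> float:
    """Transitivity: 3 * triangles / connected triples on the undirected
    simple graph; 0 when there are no connected triples."""
    return float(nx.transitivity(undirected_simple(net)))


MEASURES = ("in_degree", "out_degree", "degree", "closeness", "betweenness")


@dataclass
class CentralityTable:
    measure: str
    scores: dict[EntityId, float]
    n_nodes_used: int
    restricted_to_largest_component: bool = False

    def ranked(self) -> list[tuple[EntityId, float]]:
        """All nodes sorted by (score desc, type asc, id asc)."""
        return sorted(self.scores.items(), key=lambda kv: (-kv[1], _key(kv[0])))


def centrality(net: EntityCitationNetwork, measure: str) -> CentralityTable:
    """Node centralities.

    Degrees count distinct arcs on the directed loopful view; ``degree`` is
    in + out.  Closeness is Freeman-normalized, (N-1)/sum of distances, and
    betweenness is the unnormalized geodesic-fraction sum over unordered
    pairs, both on the undirected simple graph (largest component when
    disconnected, flagged in the result).
    """
    if measure not in MEASURES:
        raise StatsError(f"unsupported measure {measure!r}; expected one of {MEASURES}")
    if measure in ("in_degree", "out_degree", "degree"):
        indeg: Counter = Counter({v: 0 for v in net.nodes})
        outdeg: Counter = Counter({v: 0 for v in net.nodes})
        for a, b in net.weights:
            outdeg[a] += 1
            indeg[b] += 1
        if measure == "in_degree":
            scores = {v: float(indeg[v]) for v in net.nodes}
        elif measure == "out_degree":
            scores = {v: float(outdeg[v]) for v in net.nodes}
        else:
            scores = {v: float(indeg[v] + outdeg[v]) for v in net.nodes}
        return CentralityTable(measure, scores, net.n)
    g = undirected_simple(net)
    restricted = False
    if g.number_of_nodes() > 0 and not nx.is_connected(g):
        comps = weak_components(net)
        g = g.subgraph(comps[0]).copy()
        restricted = True
    if measure == "closeness":
        raw = nx.closeness_centrality(g)
        scores = {v: float(s) for v, s in raw.items()}
    else:
        raw = nx.betweenness_centrality(g, normalized=False)
        scores = {v: float(s) for v, s in raw.items()}
    return CentralityTable(measure, scores, g.number_of_nodes(), restricted)


def top_k_table(table: CentralityTable, k: int) -> dict[str, list[tuple[EntityId, float]]]:
    """Per-type (DISEASE, DRUG, GENE) and combined ("All") top-k lists."""
    if k < 1:
        raise StatsError("k must be >= 1")
    ranked = table.ranked()
    out: dict[str, list[tuple[EntityId, float]]] = {t.value: [] for t in EntityType}
    out["All"] = ranked[:k]
    for e, s in ranked:
        lst = out[e.entity_type.value]
        if len(lst) < k:
            lst.append((e, s))
    return out


@dataclass
class GraphStats:
    n: int
    m: int
    loop_count: int
    total_weight: int
    density: float
    component_sizes: list[int]
    bicomponent_sizes: list[int]
    max_core_k: int
    max_core_size: int
    mean_distance: float | None
    diameter: int | None
    diameter_pair: tuple[str, str] | None
    clustering: float
    in_degree_hist: dict[int, int]
    out_degree_hist: dict[int, int]
    in_power_law_gamma: float | None
    out_power_law_gamma: float | None

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["in_degree_hist"] = {str(k): v for k, v in self.in_degree_hist.items()}
        d["out_degree_hist"] = {str(k): v for k, v in self.out_degree_hist.items()}
        if self.diameter_pair is not None:
            d["diameter_pair"] = list(self.diameter_pair)
        return d


def compute_stats(net: EntityCitationNetwork, *, power_law_xmin: int = 1) -> GraphStats:
    """One-call macro/meso summary of the network."""
    comps = weak_components(net)
    bicomps = bicomponents(net)
    core = kcore(net)
    in_hist, out_hist = degree_distributions(net)
    mean_d = diam = pair = None
    if net.n >= 2:
        ds = distance_stats(net)
        mean_d, diam = ds.mean_distance, ds.diameter
        pair = (ds.diameter_pair[0].label, ds.diameter_pair[1].label)
    gamma_in = gamma_out = None
    for hist, attr in ((in_hist, "in"), (out_hist, "out")):
        try:
            fit = fit_power_law(hist, xmin=power_law_xmin)
        except StatsError:
            fit = None
        if attr == "in":
            gamma_in = fit.gamma if fit else None
        else:
            gamma_out = fit.gamma if fit else None
    return GraphStats(
        n=net.n,
        m=net.m,
        loop_count=net.loop_count,
        total_weight=net.total_weight,
        density=density(net) if net.n else 0.0,
        component_sizes=[len(c) for c in comps],
        bicomponent_sizes=[len(c) for c in bicomps],
        max_core_k=core.max_core_k,
        max_core_size=len(core.max_core_members),
        mean_distance=mean_d,
        diameter=diam,
        diameter_pair=pair,
        clustering=global_clustering(net),
        in_degree_hist=in_hist,
        out_degree_hist=out_hist,
        in_power_law_gamma=gamma_in,
        out_power_law_gamma=gamma_out,
    )
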