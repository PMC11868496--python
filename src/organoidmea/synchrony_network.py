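"""Spike-train synchrony scoring and functional network inference.

The synchrony between two electrodes is quantified with the
SPIKE-distance, a time-resolved, parameter-free dissimilarity between
spike trains (0 for identical trains).  With auxiliary spikes appended at
0 and T to both trains, the instantaneous dissimilarity at time t is

    S_n(t) = (dtP_n * xF_n + dtF_n * xP_n) / xISI_n            (per train)
    S(t)   = (S_1 * xISI_2 + S_2 * xISI_1) / (2 * <xISI>^2)

where tP_n / tF_n are the previous / following spikes of train n, xP_n =
t - tP_n, xF_n = tF_n - t, xISI_n = tF_n - tP_n, and dtP_n (dtF_n) is the
distance from tP_n (tF_n) to the nearest spike of the other train.  The
distance is D = (1/T) * integral of S(t); S is piecewise linear between
pooled spike times, so the integral is evaluated exactly by trapezoids on
that partition.

The synchronization score normalizes D by the mean SPIKE-distance of
random uniform spike-train pairs with the same spike counts and subtracts
from one:  score = clip(1 - D / <D_baseline>, 0, 1).  A score of 1 means
perfect synchrony, 0 chance level.  Electrode pairs scoring at least the
edge threshold (default 0.5) become weighted edges of the functional
network, on which Louvain modularity optimization identifies neural
communities; summary metrics (degrees, edge counts, community counts and
sizes) track network maturation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from ._types import ChannelMeta, SpikeTrain

__all__ = [
    "SyncParams",
    "SyncMatrix",
    "NetworkMetrics",
    "LouvainResult",
    "NO_COMMUNITY",
    "spike_distance",
    "baseline_distance_mean",
    "sync_score",
    "sync_matrix",
    "build_network",
    "louvain_communities",
    "modularity",
    "network_metrics",
    "export_network_map",
    "read_network_map",
]

logger = logging.getLogger(__name__)

#: Community label of isolated nodes and singleton-community members.
NO_COMMUNITY = -1


@dataclass(frozen=True)
class SyncParams:
    """Synchronization-scoring and network-construction parameters.

    ``n_baseline`` random uniform train pairs define the chance-level
    SPIKE-distance; ``edge_threshold`` is the minimum score for an edge
    (a score exactly at the threshold is retained); channels with fewer
    than ``min_spikes_active`` spikes are excluded as inactive.
    """

    n_baseline: int = 1000
    edge_threshold: float = 0.5
    min_spikes_active: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_baseline < 1:
            raise ValueError("n_baseline must be at least 1")
        if not 0 <= self.edge_threshold <= 1:
            raise ValueError("edge_threshold must lie in [0, 1]")


@dataclass
class SyncMatrix:
    """Symmetric pairwise synchronization scores over active channels."""

    scores: np.ndarray
    active: list[int]

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        k = len(self.active)
        if self.scores.shape != (k, k):
            raise ValueError("score matrix shape must match active channel count")
        if k and not np.allclose(self.scores, self.scores.T):
            raise ValueError("score matrix must be symmetric")


@dataclass
class LouvainResult:
    """Community labels per node plus the modularity of the partition."""

    labels: dict
    modularity: float | None


@dataclass
class NetworkMetrics:
    """Maturation-tracking summary of one functional network."""

    avg_degree: float
    total_edges: int
    n_connected_nodes: int
    n_communities: int
    n_nodes_no_community: int
    avg_community_size: float
    max_community_size: int


# ---------------------------------------------------------------------------
# SPIKE-distance


def _as_times(train, T=None):
    if isinstance(train, SpikeTrain):
        return np.asarray(train.times, dtype=float), float(train.duration)
    if T is None:
        raise ValueError("duration T required when passing bare time arrays")
    return np.asarray(train, dtype=float), float(T)


def _augment(times: np.ndarray, T: float) -> np.ndarray:
    """Sorted unique times with auxiliary spikes at 0 and T."""
    return np.unique(np.concatenate(([0.0], times, [T])))


def _nearest_dist(vals: np.ndarray, other: np.ndarray) -> np.ndarray:
    """Distance from each value to the nearest element of ``other``."""
    idx = np.searchsorted(other, vals)
    lo = other[np.clip(idx - 1, 0, other.size - 1)]
    hi = other[np.clip(idx, 0, other.size - 1)]
    return np.minimum(np.abs(vals - lo), np.abs(vals - hi))


def spike_distance(t1, t2, T: float | None = None) -> float:
    """SPIKE-distance between two spike trains on a common interval [0, T].

    Accepts two :class:`SpikeTrain` objects (sharing ``duration``) or two
    bare time arrays plus ``T``.  The piecewise-linear dissimilarity
    profile is integrated exactly between pooled spike times.  Returns a
    value >= 0 which is 0 iff the trains are identical.

    Raises
    ------
    ValueError
        If either train is empty (the pair is inactive) or the durations
        disagree.
    """
    x1, T1 = _as_times(t1, T)
    x2, T2 = _as_times(t2, T)
    if not np.isclose(T1, T2):
        raise ValueError(f"trains must share duration, got {T1} and {T2}")
    if x1.size == 0 or x2.size == 0:
        raise ValueError("SPIKE-distance undefined for an empty train")
    Tv = T1
    a1 = _augment(x1, Tv)
    a2 = _augment(x2, Tv)

    pool = np.union1d(a1, a2)
    lo = pool[:-1]
    hi = pool[1:]

    def train_quantities(tr, other):
        iP = np.searchsorted(tr, lo, side="right") - 1
        tP = tr[iP]
        tF = tr[iP + 1]
        dP = _nearest_dist(tP, other)
        dF = _nearest_dist(tF, other)
        xisi = tF - tP
        return tP, tF, dP, dF, xisi

    tP1, tF1, dP1, dF1, xisi1 = train_quantities(a1, a2)
    tP2, tF2, dP2, dF2, xisi2 = train_quantities(a2, a1)

    def S_n(t, tP, tF, dP, dF, xisi):
        return (dP * (tF - t) + dF * (t - tP)) / xisi

    mean_isi = 0.5 * (xisi1 + xisi2)
    denom = 2.0 * mean_isi**2

    def S(t):
        s1 = S_n(t, tP1, tF1, dP1, dF1, xisi1)
        s2 = S_n(t, tP2, tF2, dP2, dF2, xisi2)
        return (s1 * xisi2 + s2 * xisi1) / denom

    integral = float(np.sum(0.5 * (S(lo) + S(hi)) * (hi - lo)))
    return integral / Tv


def baseline_distance_mean(
    n1: int, n2: int, T: float, n_baseline: int, rng: np.random.Generator
) -> float:
    """Mean SPIKE-distance over random uniform train pairs.

    Each baseline pair consists of two sorted uniform-random trains on
    [0, T] with ``n1`` and ``n2`` spikes, matching the observed pair's
    spike counts so the normalization reflects timing structure rather
    than firing rate.
    """
    vals = np.empty(n_baseline)
    for k in range(n_baseline):
        u1 = np.sort(rng.uniform(0.0, T, n1))
        u2 = np.sort(rng.uniform(0.0, T, n2))
        vals[k] = spike_distance(u1, u2, T)
    return float(np.mean(vals))


def sync_score(
    t1,
    t2,
    p: SyncParams = SyncParams(),
    T: float | None = None,
    rng: np.random.Generator | None = None,
) -> float:
    """Baseline-normalized synchronization score in [0, 1].

    score = clip(1 - D(t1, t2) / <D_baseline>, 0, 1) where the baseline
    mean is over ``p.n_baseline`` spike-count-matched uniform random
    pairs.  Identical trains score exactly 1; independent random trains
    score near 0 (negative excursions are clipped to 0).  Deterministic
    given ``p.seed`` (or an explicit ``rng``).
    """
    x1, T1 = _as_times(t1, T)
    x2, _ = _as_times(t2, T if T is not None else T1)
    if x1.size < p.min_spikes_active or x2.size < p.min_spikes_active:
        raise ValueError(
            f"inactive pair: {x1.size} and {x2.size} spikes "
            f"(minimum {p.min_spikes_active})"
        )
    if rng is None:
        rng = np.random.default_rng(p.seed)
    D = spike_distance(x1, x2, T1)
    base = baseline_distance_mean(x1.size, x2.size, T1, p.n_baseline, rng)
    if base == 0.0:
        raise ValueError("degenerate baseline: mean random SPIKE-distance is 0")
    return float(np.clip(1.0 - D / base, 0.0, 1.0))


def sync_matrix(
    trains: list[SpikeTrain], p: SyncParams = SyncParams()
) -> SyncMatrix:
    """Pairwise synchronization scores over all active channels.

    Channels with fewer than ``p.min_spikes_active`` spikes are dropped.
    Baseline means are cached per unordered spike-count pair, which keeps
    the 1000-surrogate normalization affordable across many electrode
    pairs.  The diagonal is 1 by definition.
    """
    active = [tr for tr in trains if tr.n_spikes >= p.min_spikes_active]
    k = len(active)
    ids = [tr.channel for tr in active]
    scores = np.eye(k)
    if k < 2:  # no pairs to score
        return SyncMatrix(scores=np.zeros((0, 0)), active=[])
    rng = np.random.default_rng(p.seed)
    base_cache: dict[tuple[int, int], float] = {}
    T = active[0].duration
    for i in range(k):
        for j in range(i + 1, k):
            ni, nj = active[i].n_spikes, active[j].n_spikes
            key = (min(ni, nj), max(ni, nj))
            if key not in base_cache:
                base_cache[key] = baseline_distance_mean(
                    key[0], key[1], T, p.n_baseline, rng
                )
            D = spike_distance(active[i], active[j])
            s = float(np.clip(1.0 - D / base_cache[key], 0.0, 1.0))
            scores[i, j] = scores[j, i] = s
    logger.info(
        "sync_matrix: %d active channels, %d baseline count-pairs",
        k, len(base_cache),
    )
    return SyncMatrix(scores=scores, active=ids)


# ---------------------------------------------------------------------------
# Network construction, communities, metrics


def build_network(
    sync: SyncMatrix,
    channels: list[ChannelMeta] | None = None,
    p: SyncParams = SyncParams(),
) -> nx.Graph:
    """Thresholded weighted graph over active electrodes.

    Nodes carry electrode coordinates (x, y, height); pairs whose score
    is at least ``p.edge_threshold`` become edges weighted by the score
    (scores exactly at the threshold are retained).
    """
    meta = {c.id: c for c in channels} if channels else {}
    g = nx.Graph()
    for ch in sync.active:
        c = meta.get(ch)
        g.add_node(
            ch,
            x=float(c.x) if c else 0.0,
            y=float(c.y) if c else 0.0,
            height=float(c.height) if c else 0.0,
        )
    k = len(sync.active)
    for i in range(k):
        for j in range(i + 1, k):
            s = sync.scores[i, j]
            if s >= p.edge_threshold:
                g.add_edge(sync.active[i], sync.active[j], weight=float(s))
    return g


def modularity(g: nx.Graph, communities: list[set]) -> float:
    """Weighted Newman modularity Q of a partition.

    Q = (1/2m) * sum_ij [A_ij - k_i k_j / 2m] delta(c_i, c_j), with edge
    weights; computed directly from the adjacency structure (independent
    of the optimizer).
    """
    m2 = 2.0 * g.size(weight="weight")
    if m2 == 0:
        raise ValueError("modularity undefined for a graph with no edges")
    deg = dict(g.degree(weight="weight"))
    q = 0.0
    for comm in communities:
        for u in comm:
            for v in comm:
                w = g[u][v]["weight"] if g.has_edge(u, v) else 0.0
                q += w - deg[u] * deg[v] / m2
    return q / m2


def louvain_communities(g: nx.Graph, seed: int = 0,
                        n_restarts: int = 10) -> LouvainResult:
    """Louvain modularity-optimizing community detection.

    Runs two-phase Louvain (greedy local moves, then aggregation, to
    convergence) ``n_restarts`` times with seeds derived from ``seed``
    and keeps the best-modularity partition; Louvain is a greedy
    heuristic and single runs can stall in local optima on graphs with
    weak structure.  Deterministic given ``seed``.  Isolated nodes and
    members of singleton communities are labelled :data:`NO_COMMUNITY`;
    remaining communities get contiguous ids ordered by their smallest
    node.  A graph with no edges leaves every node without a community
    and an undefined (None) modularity.
    """
    labels = {node: NO_COMMUNITY for node in g.nodes}
    if g.number_of_edges() == 0:
        return LouvainResult(labels=labels, modularity=None)
    parts, q = None, -np.inf
    for r in range(max(1, n_restarts)):
        cand = nx.community.louvain_communities(
            g, weight="weight", seed=seed * 1000 + r)
        q_cand = modularity(g, cand)
        if q_cand > q:
            parts, q = cand, q_cand
    real = sorted(
        (comm for comm in parts if len(comm) > 1), key=lambda c: min(c)
    )
    for cid, comm in enumerate(real):
        for node in comm:
            labels[node] = cid
    return LouvainResult(labels=labels, modularity=q)


def assign_communities(g: nx.Graph, result: LouvainResult) -> nx.Graph:
    """Write community labels and degrees onto the graph nodes (in place)."""
    for node in g.nodes:
        g.nodes[node]["community"] = int(result.labels[node])
        g.nodes[node]["degree"] = int(g.degree(node))
    return g


def network_metrics(g: nx.Graph) -> NetworkMetrics:
    """Maturation metrics of a community-labelled network.

    Requires nodes to carry a ``community`` attribute (see
    :func:`assign_communities`); community sizes count only real (non
    ``NO_COMMUNITY``) communities.
    """
    n_nodes = g.number_of_nodes()
    total_edges = g.number_of_edges()
    degrees = [d for _, d in g.degree()]
    comm_labels = [g.nodes[n].get("community", NO_COMMUNITY) for n in g.nodes]
    sizes: dict[int, int] = {}
    for c in comm_labels:
        if c != NO_COMMUNITY:
            sizes[c] = sizes.get(c, 0) + 1
    return NetworkMetrics(
        avg_degree=float(np.mean(degrees)) if degrees else 0.0,
        total_edges=total_edges,
        n_connected_nodes=int(sum(d > 0 for d in degrees)),
        n_communities=len(sizes),
        n_nodes_no_community=int(sum(c == NO_COMMUNITY for c in comm_labels)),
        avg_community_size=float(np.mean(list(sizes.values()))) if sizes else 0.0,
        max_community_size=max(sizes.values()) if sizes else 0,
    )


def export_network_map(g: nx.Graph, path) -> None:
    """Write the network as GraphML with positional and community attributes.

    Nodes without a community are encoded with the attribute value
    ``"none"``; edge weights are the synchronization scores.
    """
    out = nx.Graph()
    for node, data in g.nodes(data=True):
        comm = data.get("community", NO_COMMUNITY)
        out.add_node(
            node,
            x=float(data.get("x", 0.0)),
            y=float(data.get("y", 0.0)),
            height=float(data.get("height", 0.0)),
            community="none" if comm == NO_COMMUNITY else str(int(comm)),
            degree=int(g.degree(node)),
        )
    for u, v, data in g.edges(data=True):
        out.add_edge(u, v, weight=float(data["weight"]))
    nx.write_graphml(out, path)


def read_network_map(path) -> nx.Graph:
    """Read a GraphML network map, restoring integer node ids and labels."""
    raw = nx.read_graphml(path)
    g = nx.Graph()
    for node, data in raw.nodes(data=True):
        comm = data.get("community", "none")
        g.add_node(
            int(node),
            x=float(data.get("x", 0.0)),
            y=float(data.get("y", 0.0)),
            height=float(data.get("height", 0.0)),
            community=NO_COMMUNITY if comm == "none" else int(comm),
            degree=int(data.get("degree", 0)),
        )
    for u, v, data in raw.edges(data=True):
        g.add_edge(int(u), int(v), weight=float(data["weight"]))
    return g
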