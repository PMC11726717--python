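"""Contact-gated dynamical network analysis.

Nodes are Cα residues; an edge joins two non-consecutive residues whose
contact persistency over the merged replicas reaches the gate threshold
(default: within 4.5 Å in at least 75% of frames).  Each edge carries the
correlation of motion C_ij of its residues and the information-transfer
weight

    W_ij = -log(|C_ij|)

so strongly correlated residues are "close" in path terms.  The
logarithm base is configurable and provably irrelevant to path node
sequences, betweenness ranking and communities: changing base rescales
every weight by one constant.

Community detection is Girvan–Newman: edges of highest weighted-path
betweenness are removed iteratively and the partition of maximum
modularity over the hierarchy is returned.  Betweenness uses W as the
path length; modularity uses the correlation magnitude |C| as the
connection strength (falling back to unit strength when absent), which
keeps both base-invariant.  Tie-breaks are lexicographic throughout so
results are reproducible.
"""

from __future__ import annotations

import heapq
import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Hashable, Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .io import Selection, Trajectory
from .metrics import ContactTable, superpose

logger = logging.getLogger(__name__)

__all__ = [
    "CorrelationMatrix",
    "NetworkBuildParams",
    "DynamicalNetwork",
    "Path",
    "PathEnsemble",
    "CommunityPartition",
    "NoPathError",
    "correlation_matrix",
    "build_network",
    "shortest_path",
    "suboptimal_paths",
    "edge_betweenness",
    "detect_communities",
    "subnetwork",
    "compare_networks",
]


class NoPathError(RuntimeError):
    """Raised when source and sink are disconnected."""


@dataclass
class CorrelationMatrix:
    """Residue-indexed correlation of motion C_ij."""

    resids: np.ndarray
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.resids)
        if self.matrix.shape != (n, n):
            raise ValueError("correlation matrix shape does not match residues")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-10):
            raise ValueError("correlation matrix must be symmetric")
        if np.abs(self.matrix).max() > 1 + 1e-9:
            raise ValueError("correlations must lie in [-1, 1]")

    def value(self, res_i: int, res_j: int) -> float:
        i = int(np.flatnonzero(self.resids == res_i)[0])
        j = int(np.flatnonzero(self.resids == res_j)[0])
        return float(self.matrix[i, j])


@dataclass(frozen=True)
class NetworkBuildParams:
    """Gates and weighting options for network construction."""

    contact_cutoff: float = 4.5  # Å, used upstream when contacts are computed
    persistency_threshold: float = 75.0  # %
    exclude_consecutive: bool = True
    corr_floor: float = 1e-6  # |C| below this would give effectively infinite W
    log_base: float = math.e

    def __post_init__(self) -> None:
        if not (0.0 < self.persistency_threshold <= 100.0):
            raise ValueError("persistency threshold must be in (0, 100]")
        if not (0.0 <= self.corr_floor < 1.0):
            raise ValueError("correlation floor must be in [0, 1)")
        if self.log_base <= 1.0:
            raise ValueError("log base must exceed 1")


@dataclass
class DynamicalNetwork:
    """Weighted residue graph with provenance.

    Edge attributes: ``corr`` = |C_ij|, ``weight`` = −log(|C_ij|) ≥ 0.
    """

    graph: nx.Graph
    condition: str = ""
    n_frames: int | None = None

    def __post_init__(self) -> None:
        for u, v, data in self.graph.edges(data=True):
            if u == v:
                raise ValueError("self-edges are not allowed")
            if data.get("weight", 0.0) < -1e-12:
                raise ValueError("edge weights must be non-negative")

    @property
    def nodes(self) -> list:
        return sorted(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_list(self) -> pd.DataFrame:
        rows = [
            dict(i=u, j=v, corr=d.get("corr", float("nan")), weight=d["weight"])
            for u, v, d in sorted(self.graph.edges(data=True))
        ]
        return pd.DataFrame(rows, columns=["i", "j", "corr", "weight"])


@dataclass
class Path:
    nodes: tuple
    cost: float


@dataclass
class PathEnsemble:
    """Optimal and suboptimal paths with per-edge usage counts.

    The per-edge usage count across the ensemble is the "structural
    information" rendered as edge thickness in network figures; this is
    a convention of the suboptimal-path methodology, recorded here in
    metadata rather than asserted as unique.
    """

    source: Hashable
    sink: Hashable
    optimal: Path
    paths: list[Path]
    edge_usage: dict[tuple, int]
    tolerance: float
    truncated: bool = False
    convention: str = "edge usage count over suboptimal-path ensemble"

    @property
    def total_usage(self) -> int:
        return sum(self.edge_usage.values())


@dataclass
class CommunityPartition:
    labels: dict
    modularity: float

    def __post_init__(self) -> None:
        if not (-1.0 - 1e-9 <= self.modularity <= 1.0 + 1e-9):
            raise ValueError("modularity outside [-1, 1]")

    def communities(self) -> list[set]:
        out: dict[int, set] = {}
        for node, lab in self.labels.items():
            out.setdefault(lab, set()).add(node)
        return [out[k] for k in sorted(out)]


# ---------------------------------------------------------------------------
# Correlation of motion


def correlation_matrix(
    trajectories: Trajectory | Sequence[Trajectory],
    ca_selection: Selection,
    fit_selection: Selection | None = None,
) -> CorrelationMatrix:
    """Correlation of motion over merged, superposed frames.

    C_ij = <Δr_i · Δr_j> / sqrt(<Δr_i²><Δr_j²>) with Δr the displacement
    of a residue's Cα from its time-mean position.  Replicas are merged
    before the mean is taken, matching per-condition pooling of replicas.
    """
    if isinstance(trajectories, Trajectory):
        trajectories = [trajectories]
    top = trajectories[0].topology
    frames = np.concatenate([t.coordinates for t in trajectories], axis=0)
    if frames.shape[0] < 2:
        raise ValueError("correlation needs >= 2 merged frames")
    if fit_selection is not None:
        ref = frames[0]
        frames = np.stack([superpose(f, ref, fit_selection)[0] for f in frames])
    idx = ca_selection.index_array
    resids = top.resids[idx]
    if len(set(resids.tolist())) != len(resids):
        raise ValueError("Cα selection must resolve one atom per residue")
    x = frames[:, idx, :]  # (T, N, 3)
    dx = x - x.mean(axis=0)
    inner = np.einsum("tik,tjk->ij", dx, dx) / dx.shape[0]
    var = np.diag(inner).copy()
    zero = np.flatnonzero(var <= 0)
    if zero.size:
        raise ValueError(f"zero-variance residue(s): {resids[zero].tolist()}")
    c = inner / np.sqrt(np.outer(var, var))
    c = np.clip((c + c.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(c, 1.0)
    return CorrelationMatrix(resids=resids.astype(int), matrix=c)


# ---------------------------------------------------------------------------
# Network construction


def build_network(
    corr: CorrelationMatrix,
    contacts: ContactTable,
    params: NetworkBuildParams | None = None,
    condition: str = "",
) -> DynamicalNetwork:
    """Gate edges by contact persistency and weight them by −log|C_ij|.

    An edge (i, j) exists iff persistency >= threshold (the boundary
    value itself passes), |i − j| > 1 when consecutive exclusion is on,
    and |C_ij| exceeds the correlation floor; pairs below the floor are
    dropped with a warning since their weight would be effectively
    infinite.
    """
    params = params or NetworkBuildParams()
    known = set(int(r) for r in corr.resids)
    contact_res = contacts.residues
    if contact_res and not (known & contact_res):
        raise ValueError("correlation matrix and contact table share no residues")
    g = nx.Graph()
    g.add_nodes_from(sorted(known))
    for row in contacts.table.itertuples():
        i, j = int(row.res_a), int(row.res_b)
        if i == j or i not in known or j not in known:
            continue
        if row.persistency < params.persistency_threshold:
            continue
        if params.exclude_consecutive and abs(i - j) == 1:
            continue
        c = abs(corr.value(i, j))
        if c <= params.corr_floor:
            logger.warning(
                "pair (%d, %d) gated in but |C|=%.2e below floor: edge dropped", i, j, c
            )
            continue
        weight = -math.log(c) / math.log(params.log_base)
        a, b = min(i, j), max(i, j)
        g.add_edge(a, b, corr=c, weight=weight, persistency=float(row.persistency))
    return DynamicalNetwork(graph=g, condition=condition, n_frames=sum(contacts.frames_per_replica))


# ---------------------------------------------------------------------------
# Paths


def _dijkstra(g: nx.Graph, source: Hashable) -> dict:
    dist = {source: 0.0}
    heap = [(0.0, source)]
    while heap:
        d, u = heapq.heappop(heap)
        if d > dist.get(u, math.inf):
            continue
        for v, data in g[u].items():
            nd = d + data["weight"]
            if nd < dist.get(v, math.inf) - 1e-15:
                dist[v] = nd
                heapq.heappush(heap, (nd, v))
    return dist


def shortest_path(net: DynamicalNetwork, source: Hashable, sink: Hashable) -> Path:
    """Minimum-total-weight path; lexicographically smallest among ties."""
    g = net.graph
    for node in (source, sink):
        if node not in g:
            raise KeyError(f"node {node!r} not in network")
    dist_s = _dijkstra(g, source)
    if sink not in dist_s:
        raise NoPathError(f"no path between {source!r} and {sink!r}")
    dist_t = _dijkstra(g, sink)
    opt = dist_s[sink]
    # walk from source, always taking the smallest-labelled neighbour that
    # stays on some optimal path
    path = [source]
    node = source
    seen = {source}
    while node != sink:
        candidates = [
            v
            for v, data in g[node].items()
            if v not in seen
            and abs(dist_s[node] + data["weight"] + dist_t.get(v, math.inf) - opt) < 1e-9
        ]
        node = min(candidates)
        seen.add(node)
        path.append(node)
    return Path(nodes=tuple(path), cost=float(opt))


def suboptimal_paths(
    net: DynamicalNetwork,
    source: Hashable,
    sink: Hashable,
    tolerance: float,
    max_paths: int = 10_000,
) -> PathEnsemble:
    """All simple paths within ``tolerance`` of the optimal cost.

    Depth-first enumeration pruned by the exact cost-to-go lower bound;
    the ensemble is truncated (and flagged) if ``max_paths`` is reached.
    Per-edge usage counts across the ensemble quantify how much
    structural information flows through each edge.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    optimal = shortest_path(net, source, sink)
    budget = optimal.cost + tolerance + 1e-12
    g = net.graph
    dist_t = _dijkstra(g, sink)

    paths: list[Path] = []
    truncated = False
    stack = [source]
    on_path = {source}

    def dfs(node: Hashable, cost: float) -> bool:
        nonlocal truncated
        if node == sink:
            paths.append(Path(nodes=tuple(stack), cost=cost))
            if len(paths) >= max_paths:
                truncated = True
                return False
            return True
        for v in sorted(g[node]):
            if v in on_path:
                continue
            nc = cost + g[node][v]["weight"]
            if nc + dist_t.get(v, math.inf) > budget:
                continue
            stack.append(v)
            on_path.add(v)
            ok = dfs(v, nc)
            stack.pop()
            on_path.remove(v)
            if not ok:
                return False
        return True

    dfs(source, 0.0)
    paths.sort(key=lambda p: (p.cost, p.nodes))
    usage: dict[tuple, int] = {}
    for p in paths:
        for u, v in zip(p.nodes[:-1], p.nodes[1:]):
            key = (min(u, v), max(u, v))
            usage[key] = usage.get(key, 0) + 1
    if truncated:
        logger.warning("suboptimal path ensemble truncated at %d paths", max_paths)
    return PathEnsemble(
        source=source,
        sink=sink,
        optimal=paths[0] if paths else optimal,
        paths=paths,
        edge_usage=usage,
        tolerance=tolerance,
        truncated=truncated,
    )


def edge_betweenness(net: DynamicalNetwork) -> dict[tuple, float]:
    """Weighted shortest-path edge betweenness over unordered node pairs.

    When several shortest paths tie, each carries an equal fraction of
    the pair's unit of flow.
    """
    if net.graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    raw = nx.edge_betweenness_centrality(net.graph, weight="weight", normalized=False)
    return {(min(u, v), max(u, v)): float(s) for (u, v), s in raw.items()}


# ---------------------------------------------------------------------------
# Communities


def _strength_weight(g: nx.Graph) -> str | None:
    return "corr" if all("corr" in d for _, _, d in g.edges(data=True)) else None


def _partition_of(g: nx.Graph) -> list[set]:
    return sorted((set(c) for c in nx.connected_components(g)), key=lambda c: sorted(c)[0])


def detect_communities(net: DynamicalNetwork) -> CommunityPartition:
    """Girvan–Newman partition at maximum weighted modularity.

    Edges of highest weighted-path betweenness are removed one at a time
    (ties broken by lexicographic edge label); every partition in the
    removal hierarchy is scored by modularity with |C| connection
    strength and the best is returned.  Deterministic by construction.
    """
    g0 = net.graph
    if g0.number_of_nodes() == 0:
        raise ValueError("empty graph")
    strength = _strength_weight(g0)
    work = g0.copy()
    best = _partition_of(work)
    best_q = nx.algorithms.community.modularity(g0, best, weight=strength) if g0.number_of_edges() else 0.0
    while work.number_of_edges():
        bc = nx.edge_betweenness_centrality(work, weight="weight", normalized=False)
        top_score = max(bc.values())
        u, v = min(
            (min(e), max(e)) for e, s in bc.items() if abs(s - top_score) < 1e-9
        )
        work.remove_edge(u, v)
        partition = _partition_of(work)
        q = nx.algorithms.community.modularity(g0, partition, weight=strength)
        if q > best_q + 1e-12:
            best, best_q = partition, q
    labels = {node: k for k, comm in enumerate(best) for node in comm}
    return CommunityPartition(labels=labels, modularity=float(best_q))


def subnetwork(
    net: DynamicalNetwork, residues: Iterable[Hashable]
) -> tuple[DynamicalNetwork, dict]:
    """Induced subgraph on a residue set, with a comparison summary."""
    residues = set(residues)
    present = residues & set(net.graph.nodes)
    if not present:
        raise ValueError("residue set induces an empty subnetwork")
    sub = net.graph.subgraph(sorted(present)).copy()
    out = DynamicalNetwork(graph=sub, condition=net.condition, n_frames=net.n_frames)
    summary = dict(
        condition=net.condition,
        n_nodes=sub.number_of_nodes(),
        n_edges=sub.number_of_edges(),
        total_weight=float(sum(d["weight"] for _, _, d in sub.edges(data=True))),
        mean_corr=float(np.mean([d["corr"] for _, _, d in sub.edges(data=True)]))
        if sub.number_of_edges()
        else float("nan"),
    )
    return out, summary


def compare_networks(a: DynamicalNetwork, b: DynamicalNetwork) -> pd.DataFrame:
    """Classify edges as gained/lost/common between conditions A and B.

    Common edges are annotated with ΔW = W_A − W_B.
    """
    nodes_a, nodes_b = set(a.graph.nodes), set(b.graph.nodes)
    if nodes_a and nodes_b and not (nodes_a & nodes_b):
        raise ValueError("networks share no nodes")
    edges_a = {(min(u, v), max(u, v)): d for u, v, d in a.graph.edges(data=True)}
    edges_b = {(min(u, v), max(u, v)): d for u, v, d in b.graph.edges(data=True)}
    rows = []
    for e in sorted(set(edges_a) | set(edges_b)):
        in_a, in_b = e in edges_a, e in edges_b
        status = "common" if in_a and in_b else ("gained" if in_a else "lost")
        dw = (
            edges_a[e]["weight"] - edges_b[e]["weight"]
            if in_a and in_b
            else float("nan")
        )
        rows.append(dict(i=e[0], j=e[1], status=status, delta_weight=dw))
    return pd.DataFrame(rows, columns=["i", "j", "status", "delta_weight"])
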