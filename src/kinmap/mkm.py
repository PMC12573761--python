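"""Molecular Kinetics Map: chi-filtered clustering and overlap graph.

The construction mirrors the Mapper algorithm from topological data
analysis, with the membership function chi as the filter: states are
covered by N_I uniform chi-intervals, each interval's states are grouped
by common-nearest-neighbor (CNN) density clustering, and clusters in
consecutive intervals are connected whenever their neighborhoods (all
states within r_n of the cluster's average structure) share states.
The resulting graph orders clusters along the reaction coordinate; its
extreme-chi nodes are the metastable macro-states and its source-to-sink
paths are candidate transition pathways.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import cdist

from .features import ConformationSet, kabsch_rmsd, mean_structure, pairwise_rmsd_matrix

__all__ = [
    "NOISE",
    "ChiPartition",
    "ClusterSet",
    "MKMNode",
    "MKMGraph",
    "Pathway",
    "EmptyGraphError",
    "partition_by_chi",
    "cnn_cluster",
    "build_mkm",
    "enumerate_pathways",
]

NOISE = -1


class EmptyGraphError(RuntimeError):
    """No clusters were found in any chi-interval."""


@dataclass(frozen=True)
class ChiPartition:
    n_intervals: int
    boundaries: np.ndarray  # (n_intervals + 1,) ascending, spanning [0, 1]
    assignment: np.ndarray  # per-state interval index

    def interval_members(self, interval: int) -> np.ndarray:
        return np.flatnonzero(self.assignment == interval)


@dataclass(frozen=True)
class ClusterSet:
    labels: np.ndarray  # per-state cluster id, NOISE = -1
    epsilon: float
    theta: int
    metric: str

    @property
    def n_clusters(self) -> int:
        labs = self.labels[self.labels != NOISE]
        return int(labs.max() + 1) if labs.size else 0


@dataclass
class MKMNode:
    node_id: int
    interval: int
    members: np.ndarray  # global state indices
    mean_chi: float
    mean_structure: np.ndarray
    weight: float = 0.0  # pi, filled by build_mkm
    neighborhood: np.ndarray = field(default=None, repr=False)

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class MKMGraph:
    nodes: list  # list[MKMNode], node_id == position
    edges: dict  # (i, j) with i < j -> shared-state count
    r_n: float
    metric: str
    n_intervals: int

    def neighbors(self, node_id: int) -> list:
        out = []
        for (i, j) in self.edges:
            if i == node_id:
                out.append(j)
            elif j == node_id:
                out.append(i)
        return sorted(out)

    @property
    def weights(self) -> np.ndarray:
        return np.array([n.weight for n in self.nodes])

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        for node in self.nodes:
            g.add_node(node.node_id, interval=node.interval,
                       mean_chi=node.mean_chi, weight=node.weight,
                       size=node.size)
        for (i, j), w in self.edges.items():
            g.add_edge(i, j, shared=int(w))
        return g

    def save_json(self, path: str | Path) -> None:
        payload = {
            "r_n": self.r_n,
            "metric": self.metric,
            "n_intervals": self.n_intervals,
            "nodes": [
                {
                    "id": n.node_id,
                    "interval": n.interval,
                    "mean_chi": n.mean_chi,
                    "weight": n.weight,
                    "members": n.members.tolist(),
                    "mean_structure": np.asarray(n.mean_structure).tolist(),
                }
                for n in self.nodes
            ],
            "edges": [
                {"source": i, "target": j, "shared": int(w)}
                for (i, j), w in sorted(self.edges.items())
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def load_json(cls, path: str | Path) -> "MKMGraph":
        payload = json.loads(Path(path).read_text())
        nodes = [
            MKMNode(
                node_id=n["id"], interval=n["interval"],
                members=np.asarray(n["members"], dtype=int),
                mean_chi=float(n["mean_chi"]),
                mean_structure=np.asarray(n["mean_structure"], dtype=float),
                weight=float(n["weight"]),
            )
            for n in payload["nodes"]
        ]
        edges = {(e["source"], e["target"]): e["shared"] for e in payload["edges"]}
        return cls(nodes=nodes, edges=edges, r_n=float(payload["r_n"]),
                   metric=payload["metric"], n_intervals=int(payload["n_intervals"]))

    def save_graphml(self, path: str | Path) -> None:
        import networkx as nx

        nx.write_graphml(self.to_networkx(), str(path))

    def export_structures(self, directory: str | Path, elements=None) -> list:
        """Write each node's average structure to an XYZ file (molecular
        maps only; requires (A, 3)-shaped mean structures)."""
        from .features import save_xyz

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        written = []
        for node in self.nodes:
            structure = np.asarray(node.mean_structure)
            if structure.ndim != 2 or structure.shape[1] != 3:
                raise ValueError(
                    "export_structures requires molecular (A, 3) structures")
            path = directory / f"node{node.node_id:03d}.xyz"
            save_xyz(path, structure, elements=elements,
                     comment=f"interval {node.interval} mean_chi {node.mean_chi:.4f}")
            written.append(path)
        return written


@dataclass(frozen=True)
class Pathway:
    """Ordered node sequence from the chi~0 cluster to the chi~1 cluster."""

    nodes: tuple

    @property
    def length(self) -> int:
        return len(self.nodes)

    def reversed(self) -> "Pathway":
        return Pathway(nodes=tuple(reversed(self.nodes)))


# ---------------------------------------------------------------------------


def partition_by_chi(chi: np.ndarray, n_intervals: int) -> ChiPartition:
    """Cover [0, 1] with ``n_intervals`` uniform half-open intervals
    [j/N, (j+1)/N), the last one closed at 1, and assign every state."""
    chi = np.asarray(chi, dtype=float)
    if n_intervals < 2:
        raise ValueError("need at least two chi-intervals")
    if np.any(chi < 0) or np.any(chi > 1):
        raise ValueError("chi values must lie in [0, 1]")
    boundaries = np.linspace(0.0, 1.0, n_intervals + 1)
    assignment = np.minimum((chi * n_intervals).astype(int), n_intervals - 1)
    return ChiPartition(n_intervals=n_intervals, boundaries=boundaries,
                        assignment=assignment)


def _distance_matrix(states: np.ndarray, metric: str) -> np.ndarray:
    if metric == "euclidean":
        flat = states.reshape(states.shape[0], -1)
        return cdist(flat, flat)
    if metric == "rmsd":
        return pairwise_rmsd_matrix(states, metric="rmsd")
    raise ValueError(f"unknown metric {metric!r}; expected 'euclidean' or 'rmsd'")


def cnn_cluster(
    states: np.ndarray | ConformationSet,
    epsilon: float,
    theta: int,
    metric: str = "euclidean",
    require_direct_neighbor: bool = True,
) -> ClusterSet:
    """Common-nearest-neighbor density clustering.

    Two states are neighbors when their distance is < epsilon (the point
    itself never counts as its own neighbor).  A density link joins a
    pair when they are neighbors AND their neighbor sets share at least
    theta states (the two points under comparison are excluded from the
    count).  Clusters are the connected components of the density-link
    relation; states participating in no link are NOISE.

    ``require_direct_neighbor=False`` switches to the looser variant
    where the shared-neighbor test alone links a pair.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    if theta < 0:
        raise ValueError("theta must be nonnegative")
    coords = states.coordinates if isinstance(states, ConformationSet) \
        else np.asarray(states, dtype=float)
    n = coords.shape[0]
    if n == 0:
        return ClusterSet(labels=np.empty(0, dtype=int), epsilon=epsilon,
                          theta=theta, metric=metric)
    if n == 1:
        return ClusterSet(labels=np.array([NOISE]), epsilon=epsilon,
                          theta=theta, metric=metric)
    dist = _distance_matrix(coords, metric)
    adj = dist < epsilon
    np.fill_diagonal(adj, False)
    # (A @ A)[i, j] counts common neighbors; the zero diagonal of A already
    # keeps i and j themselves out of the count
    shared = adj.astype(np.float32) @ adj.astype(np.float32)
    link = shared >= theta
    if require_direct_neighbor:
        link &= adj
    np.fill_diagonal(link, False)
    n_comp, comp = connected_components(csr_matrix(link), directed=False)
    labels = np.full(n, NOISE, dtype=int)
    isolated = ~link.any(axis=0)
    next_id = 0
    remap: dict[int, int] = {}
    for i in range(n):
        if isolated[i]:
            continue
        c = comp[i]
        if c not in remap:
            remap[c] = next_id
            next_id += 1
        labels[i] = remap[c]
    return ClusterSet(labels=labels, epsilon=epsilon, theta=theta, metric=metric)


def _broadcast(value, n_intervals, name) -> list:
    if np.isscalar(value):
        return [value] * n_intervals
    value = list(value)
    if len(value) != n_intervals:
        raise ValueError(f"{name} must be a scalar or one value per interval")
    return value


def build_mkm(
    states: np.ndarray | ConformationSet,
    chi: np.ndarray,
    partition: ChiPartition,
    epsilon: float | Sequence[float],
    theta: int | Sequence[int],
    r_n: float,
    metric: str = "euclidean",
    min_shared: int = 1,
    require_direct_neighbor: bool = True,
    neighborhood_mode: str = "members",
) -> MKMGraph:
    """Assemble the Molecular Kinetics Map.

    Per interval the states are CNN-clustered with that interval's
    (epsilon, theta).  Each cluster then receives a neighborhood drawn
    from the full X0 set (noise states included): with the default
    ``neighborhood_mode='members'`` it contains every state within
    ``r_n`` of *some* member of the cluster; with ``'mean'`` it contains
    every state within ``r_n`` of the cluster's average structure.  The
    member-anchored rule is the default because metastable clusters in
    consecutive chi-intervals are typically separated by much more than
    r_n between their centroids while their member clouds interdigitate
    along the transition channels — exactly the overlap an edge should
    detect.  Clusters in consecutive intervals are joined by an edge
    when their neighborhoods share at least ``min_shared`` states; the
    edge weight is the intersection size.  Node weights pi are the
    member counts normalized over all clustered (non-noise) states.
    """
    if neighborhood_mode not in ("members", "mean"):
        raise ValueError("neighborhood_mode must be 'members' or 'mean'")
    coords = states.coordinates if isinstance(states, ConformationSet) \
        else np.asarray(states, dtype=float)
    chi = np.asarray(chi, dtype=float)
    eps_list = _broadcast(epsilon, partition.n_intervals, "epsilon")
    theta_list = _broadcast(theta, partition.n_intervals, "theta")

    nodes: list[MKMNode] = []
    for interval in range(partition.n_intervals):
        idx = partition.interval_members(interval)
        if idx.size == 0:
            continue
        cs = cnn_cluster(coords[idx], epsilon=eps_list[interval],
                         theta=theta_list[interval], metric=metric,
                         require_direct_neighbor=require_direct_neighbor)
        for cid in range(cs.n_clusters):
            members = idx[cs.labels == cid]
            avg = mean_structure(coords[members], metric=metric)
            nodes.append(MKMNode(
                node_id=len(nodes), interval=interval, members=members,
                mean_chi=float(chi[members].mean()), mean_structure=avg,
            ))
    if not nodes:
        raise EmptyGraphError(
            "CNN clustering produced no clusters in any interval; "
            "check epsilon/theta against the pairwise-distance histogram"
        )

    total = sum(n.size for n in nodes)
    flat = coords.reshape(coords.shape[0], -1)
    for node in nodes:
        node.weight = node.size / total
        if neighborhood_mode == "mean":
            anchors = np.asarray(node.mean_structure)[None]
        else:
            anchors = coords[node.members]
        if metric == "euclidean":
            d = cdist(flat, anchors.reshape(len(anchors), -1)).min(axis=1)
        else:
            d = np.array([
                min(kabsch_rmsd(c, a) for a in anchors) for c in coords
            ])
        node.neighborhood = np.flatnonzero(d < r_n)

    edges: dict[tuple[int, int], int] = {}
    for a in nodes:
        for b in nodes:
            if b.node_id <= a.node_id or b.interval != a.interval + 1:
                continue
            shared = np.intersect1d(a.neighborhood, b.neighborhood,
                                    assume_unique=True).size
            if shared >= min_shared:
                edges[(a.node_id, b.node_id)] = int(shared)
    return MKMGraph(nodes=nodes, edges=edges, r_n=r_n, metric=metric,
                    n_intervals=partition.n_intervals)


def _select_extreme(nodes: list, take_max: bool) -> int:
    """Extreme-mean-chi node; ties broken by larger weight, then id."""
    key = (lambda n: (n.mean_chi, n.weight, -n.node_id)) if take_max \
        else (lambda n: (-n.mean_chi, n.weight, -n.node_id))
    return max(nodes, key=key).node_id


def enumerate_pathways(graph: MKMGraph, max_paths: int = 1000) -> list:
    """All simple source-to-sink paths with strictly increasing interval.

    Source and sink are the nodes with minimum and maximum mean chi.
    Depth-first enumeration visits neighbors in ascending node id, so
    the output ordering is deterministic; the list is truncated at
    ``max_paths`` with a warning.
    """
    if not graph.nodes:
        raise EmptyGraphError("cannot enumerate pathways of an empty graph")
    source = _select_extreme(graph.nodes, take_max=False)
    sink = _select_extreme(graph.nodes, take_max=True)
    adjacency: dict[int, list[int]] = {n.node_id: [] for n in graph.nodes}
    for (i, j) in graph.edges:
        adjacency[i].append(j)
        adjacency[j].append(i)
    for v in adjacency.values():
        v.sort()

    paths: list[Pathway] = []
    truncated = False

    def dfs(current: int, trail: list[int]) -> bool:
        nonlocal truncated
        if current == sink:
            paths.append(Pathway(nodes=tuple(trail)))
            if len(paths) >= max_paths:
                truncated = True
                return False
            return True
        for nxt in adjacency[current]:
            if nxt in trail:
                continue
            if graph.nodes[nxt].interval <= graph.nodes[current].interval:
                continue
            if not dfs(nxt, trail + [nxt]):
                return False
        return True

    if source != sink:
        dfs(source, [source])
    if truncated:
        warnings.warn(f"pathway enumeration truncated at {max_paths} paths",
                      stacklevel=2)
    if not paths:
        warnings.warn("source and sink are disconnected: no pathways found",
                      stacklevel=2)
    return paths
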