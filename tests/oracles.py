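"""Independent brute-force oracles used by the test suite.

Each function here re-derives a quantity by the most direct method
available (exhaustive search, O(n^2) counting, closed forms), sharing no
code with the implementation paths it checks.
"""

from __future__ import annotations

import itertools

import numpy as np


def brute_force_cnn(points: np.ndarray, epsilon: float, theta: int,
                    require_direct_neighbor: bool = True) -> np.ndarray:
    """Direct O(n^2) common-nearest-neighbor clustering with union-find."""
    n = len(points)
    flat = points.reshape(n, -1)
    neigh = [set() for _ in range(n)]
    for i in range(n):
        for j in range(n):
            if i != j and np.linalg.norm(flat[i] - flat[j]) < epsilon:
                neigh[i].add(j)

    parent = list(range(n))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    linked = [False] * n
    for i in range(n):
        for j in range(i + 1, n):
            shared = len((neigh[i] & neigh[j]) - {i, j})
            direct = j in neigh[i]
            if shared >= theta and (direct or not require_direct_neighbor):
                parent[find(i)] = find(j)
                linked[i] = linked[j] = True

    labels = np.full(n, -1, dtype=int)
    remap = {}
    for i in range(n):
        if not linked[i]:
            continue
        root = find(i)
        if root not in remap:
            remap[root] = len(remap)
        labels[i] = remap[root]
    return labels


def same_partition(labels_a: np.ndarray, labels_b: np.ndarray) -> bool:
    """Equality of clusterings up to label permutation (noise = -1 fixed)."""
    if (labels_a == -1).tolist() != (labels_b == -1).tolist():
        return False
    mapping = {}
    for a, b in zip(labels_a, labels_b):
        if a == -1:
            continue
        if mapping.setdefault(a, b) != b:
            return False
    return len(set(mapping.values())) == len(mapping)


def brute_force_rmsd(a: np.ndarray, b: np.ndarray, coarse: int = 24,
                     refine_rounds: int = 3) -> float:
    """Minimum RMSD over proper rotations by Euler-angle grid search with
    local refinement (translation handled by centering)."""
    from scipy.spatial.transform import Rotation

    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)

    def rmsd_for(angles):
        rot = Rotation.from_euler("zyx", angles)
        return np.sqrt(np.mean(np.sum((rot.apply(bc) - ac) ** 2, axis=1)))

    grids = [np.linspace(-np.pi, np.pi, coarse)] * 3
    best = None
    best_angles = None
    for angles in itertools.product(*grids):
        val = rmsd_for(angles)
        if best is None or val < best:
            best, best_angles = val, np.array(angles)
    width = 2 * np.pi / coarse
    for _ in range(refine_rounds):
        local = [np.linspace(c - width, c + width, 9) for c in best_angles]
        for angles in itertools.product(*local):
            val = rmsd_for(angles)
            if val < best:
                best, best_angles = val, np.array(angles)
        width /= 4.0
    return float(best)


def dihedral_by_planes(p0, p1, p2, p3) -> float:
    """Signed dihedral built explicitly from the two bond planes: the
    angle between plane normals, signed by whether the rotation from the
    first normal to the second follows the right-hand rule about the
    central bond."""
    n1 = np.cross(p1 - p0, p2 - p1)
    n2 = np.cross(p2 - p1, p3 - p2)
    n1 = n1 / np.linalg.norm(n1)
    n2 = n2 / np.linalg.norm(n2)
    cosang = np.clip(np.dot(n1, n2), -1.0, 1.0)
    angle = np.arccos(cosang)
    axis = (p2 - p1) / np.linalg.norm(p2 - p1)
    if np.dot(np.cross(n1, n2), axis) < 0:
        angle = -angle
    if angle <= -np.pi + 1e-12:
        angle = np.pi
    return float(angle)


def exhaustive_increasing_paths(n_nodes, intervals, edges, source, sink):
    """All source->sink node sequences along edges with strictly
    increasing interval index, found via networkx on the directed
    version of the graph (independent of the package's DFS)."""
    import networkx as nx

    g = nx.DiGraph()
    g.add_nodes_from(range(n_nodes))
    for (i, j) in edges:
        if intervals[i] < intervals[j]:
            g.add_edge(i, j)
        elif intervals[j] < intervals[i]:
            g.add_edge(j, i)
    if source == sink or not nx.has_path(g, source, sink):
        return []
    return [tuple(p) for p in nx.all_simple_paths(g, source, sink)]
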