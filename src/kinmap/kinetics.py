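"""Free-energy profiles and square-root-approximation (SqRA) kinetics.

Given the kinetics map with empirical cluster weights pi (Boltzmann
weights estimated from member counts), this module derives

* free energies E_i = -(1/beta) ln pi_i, plotted along pathways as a
  function of the mean chi of each node,
* SqRA transition rates on edges, k_ij = sqrt(pi_j / pi_i) with a unit
  prefactor (relative-rate convention: the geometric flux factor of the
  full SqRA is not identifiable from cluster weights alone, so all
  reported rates are comparable within one map but carry no absolute
  time unit),
* effective pathway rates, the series (harmonic-mean) composition of
  the edge rates along a source-to-sink traversal,
* the SqRA generator matrix Q with its eigenvalue spectrum, and a
  sensitivity scan of the spectrum over (N_I, epsilon, theta).

SqRA rates satisfy detailed balance pi_i k_ij = pi_j k_ji = sqrt(pi_i
pi_j) by construction, so Q is similar to a symmetric matrix and its
spectrum is real, with kappa_0 = 0 and all other eigenvalues negative.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.linalg

from .mkm import MKMGraph, Pathway, build_mkm, enumerate_pathways, partition_by_chi

__all__ = [
    "ClusterWeights",
    "FreeEnergyProfile",
    "RateMatrix",
    "SpectrumReport",
    "cluster_weights",
    "free_energy",
    "sqra_rate",
    "effective_rate",
    "pathway_rates",
    "rate_matrix",
    "sensitivity_scan",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ClusterWeights:
    """Per-node equilibrium weights pi, normalized over retained nodes."""

    pi: np.ndarray
    node_ids: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.pi <= 0):
            raise ValueError("cluster weights must be strictly positive")
        if abs(float(self.pi.sum()) - 1.0) > 1e-12:
            raise ValueError("cluster weights must sum to one")

    def of(self, node_id: int) -> float:
        return float(self.pi[int(np.flatnonzero(self.node_ids == node_id)[0])])


@dataclass(frozen=True)
class FreeEnergyProfile:
    node_ids: np.ndarray
    mean_chi: np.ndarray
    energy: np.ndarray  # units of 1/beta
    beta: float


@dataclass(frozen=True)
class RateMatrix:
    Q: np.ndarray
    node_ids: np.ndarray
    pi: np.ndarray
    prefactor: float = 1.0

    def spectrum(self, params: Optional[dict] = None) -> "SpectrumReport":
        eigvals = np.linalg.eigvals(self.Q)
        if np.max(np.abs(eigvals.imag)) > 1e-8:
            # detailed balance makes D^(1/2) Q D^(-1/2) symmetric
            # (D = diag(pi)), so its real spectrum is the exact one
            logger.info("complex eigenvalue residue detected; symmetrizing")
            s = np.sqrt(self.pi)
            sym = (s[:, None] / s[None, :]) * self.Q
            eigvals = scipy.linalg.eigvalsh(0.5 * (sym + sym.T))
        vals = np.sort(eigvals.real)[::-1]
        return SpectrumReport(eigenvalues=vals, parameters=dict(params or {}))


@dataclass(frozen=True)
class SpectrumReport:
    eigenvalues: np.ndarray  # real parts, sorted descending; kappa_0 ~ 0
    parameters: dict

    def kappa(self, k: int) -> float:
        return float(self.eigenvalues[k])


def cluster_weights(graph: MKMGraph) -> ClusterWeights:
    """Empirical Boltzmann weight of each node: member count over total
    clustered count (noise states carry no weight)."""
    sizes = np.array([n.size for n in graph.nodes], dtype=float)
    ids = np.array([n.node_id for n in graph.nodes])
    keep = sizes > 0
    if not np.all(keep):
        warnings.warn("empty nodes excluded from weights", stacklevel=2)
    sizes, ids = sizes[keep], ids[keep]
    return ClusterWeights(pi=sizes / sizes.sum(), node_ids=ids)


def free_energy(weights: ClusterWeights, beta: float = 1.0,
                graph: Optional[MKMGraph] = None) -> FreeEnergyProfile:
    """E_i = -(1/beta) ln pi_i; with the default beta = 1 the energies
    are in units of kT.  When a graph is supplied the profile is ordered
    by mean chi."""
    if beta <= 0:
        raise ValueError("beta must be positive")
    energy = -np.log(weights.pi) / beta
    chi = np.full(len(weights.pi), np.nan)
    ids = weights.node_ids.copy()
    if graph is not None:
        chi = np.array([graph.nodes[i].mean_chi for i in ids], dtype=float)
        order = np.argsort(chi)
        ids, chi, energy = ids[order], chi[order], energy[order]
    return FreeEnergyProfile(node_ids=ids, mean_chi=chi, energy=energy, beta=beta)


def sqra_rate(pi_i: float, pi_j: float, prefactor: float = 1.0) -> float:
    """SqRA rate i -> j: prefactor * sqrt(pi_j / pi_i)."""
    if pi_i <= 0 or pi_j <= 0:
        raise ValueError("SqRA rates require strictly positive weights")
    return prefactor * float(np.sqrt(pi_j / pi_i))


def effective_rate(pathway: Pathway, weights: ClusterWeights,
                   graph: Optional[MKMGraph] = None,
                   prefactor: float = 1.0) -> float:
    """Harmonic-mean composition of the edge rates along a pathway.

    k_p = (sum_i 1 / k_{p_i, p_{i+1}})^-1 — the series-resistance rule:
    the slowest link dominates.  Traverse the reversed pathway for the
    reverse rate.
    """
    if pathway.length < 2:
        raise ValueError("a pathway needs at least two nodes")
    if graph is not None:
        for a, b in zip(pathway.nodes[:-1], pathway.nodes[1:]):
            if (min(a, b), max(a, b)) not in graph.edges:
                raise ValueError(f"pathway step {a}->{b} is not an edge of the graph")
    inv = 0.0
    for a, b in zip(pathway.nodes[:-1], pathway.nodes[1:]):
        inv += 1.0 / sqra_rate(weights.of(a), weights.of(b), prefactor)
    return 1.0 / inv


def pathway_rates(pathway: Pathway, weights: ClusterWeights,
                  graph: Optional[MKMGraph] = None,
                  prefactor: float = 1.0) -> tuple[float, float]:
    """(forward, reverse) effective rates of a pathway."""
    fwd = effective_rate(pathway, weights, graph, prefactor)
    rev = effective_rate(pathway.reversed(), weights, graph, prefactor)
    return fwd, rev


def rate_matrix(graph: MKMGraph, weights: ClusterWeights,
                prefactor: float = 1.0) -> RateMatrix:
    """SqRA discretization of the generator on the kinetics map.

    Q_ij = prefactor * sqrt(pi_j / pi_i) on edges, zero elsewhere off the
    diagonal, and Q_ii = -sum_j Q_ij so rows sum to zero.
    """
    ids = weights.node_ids
    k = len(ids)
    pos = {int(node_id): idx for idx, node_id in enumerate(ids)}
    Q = np.zeros((k, k))
    for (i, j) in graph.edges:
        if i not in pos or j not in pos:
            continue
        a, b = pos[i], pos[j]
        Q[a, b] = sqra_rate(weights.pi[a], weights.pi[b], prefactor)
        Q[b, a] = sqra_rate(weights.pi[b], weights.pi[a], prefactor)
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    # connectivity diagnostic
    adj = (Q != 0).astype(int)
    np.fill_diagonal(adj, 1)
    from scipy.sparse.csgraph import connected_components
    n_comp, _ = connected_components(adj, directed=False)
    if n_comp > 1:
        warnings.warn(f"rate matrix graph has {n_comp} disconnected components",
                      stacklevel=2)
    return RateMatrix(Q=Q, node_ids=ids, pi=weights.pi.copy(), prefactor=prefactor)


def sensitivity_scan(
    states: np.ndarray,
    chi: np.ndarray,
    n_intervals_grid: Sequence[int],
    epsilon_grid: Sequence[float],
    theta_grid: Sequence[int],
    r_n: float,
    metric: str = "euclidean",
    n_eigenvalues: int = 3,
) -> pd.DataFrame:
    """Rebuild the map and its SqRA spectrum over a parameter grid.

    Returns a long-format table with one row per (N_I, epsilon, theta):
    cluster count and the leading nontrivial eigenvalues kappa_1..kappa_k
    (kappa_0 = 0 is omitted).  Grid points where clustering yields no
    graph are recorded with NaN entries rather than aborting the scan.
    """
    rows = []
    for n_int in n_intervals_grid:
        for eps in epsilon_grid:
            for theta in theta_grid:
                row = {"n_intervals": n_int, "epsilon": eps, "theta": theta,
                       "n_clusters": np.nan}
                row.update({f"kappa_{k}": np.nan for k in range(1, n_eigenvalues + 1)})
                try:
                    part = partition_by_chi(chi, n_int)
                    graph = build_mkm(states, chi, part, epsilon=eps,
                                      theta=theta, r_n=r_n, metric=metric)
                    w = cluster_weights(graph)
                    spec = rate_matrix(graph, w).spectrum(
                        {"n_intervals": n_int, "epsilon": eps, "theta": theta})
                    row["n_clusters"] = len(graph.nodes)
                    for k in range(1, n_eigenvalues + 1):
                        if k < len(spec.eigenvalues):
                            row[f"kappa_{k}"] = spec.kappa(k)
                except Exception as exc:  # record, do not abort the scan
                    logger.warning("scan point (N_I=%s, eps=%s, theta=%s) failed: %s",
                                   n_int, eps, theta, exc)
                rows.append(row)
    return pd.DataFrame(rows)
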