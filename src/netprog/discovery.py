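"""Insulated heat diffusion and subnetwork extraction over a PPI network.

Gene heat is propagated by a random walk with restart: with walk matrix
W_ij = A_ij / degree(j) and restart probability beta, the diffusion matrix
is F = beta (I - (1-beta) W)^-1, and the exchanged heat E_ij = F_ij h_j is
the heat gene i receives from gene j.  Thresholding E at delta defines a
directed graph whose strongly connected components (of at least
``min_size`` genes) are the candidate subnetworks; significance comes from
uniformly permuting the heat vector over network genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from netprog.heat import GeneHeat

logger = logging.getLogger(__name__)


@dataclass
class DiffusionResult:
    """Diffusion operator F and exchanged heat E for one network + heat vector."""

    nodes: list[str]
    beta: float
    F: np.ndarray
    heat: np.ndarray
    E: np.ndarray
    delta: float | None = None


@dataclass
class Subnetwork:
    """A discovered gene module: members, induced PPI edges, significance."""

    genes: frozenset[str]
    induced_edges: list[tuple[str, str]]
    network_label: str = ""
    size_class_p: float | None = None
    subnetwork_id: str = ""

    @property
    def size(self) -> int:
        return len(self.genes)


def insulated_diffusion(net: nx.Graph, beta: float) -> tuple[np.ndarray, list[str]]:
    """Diffusion matrix F = beta (I - (1-beta) W)^-1 and its node ordering.

    Solved as a linear system per connected component (W is column
    stochastic within a component, so the system is nonsingular for
    beta > 0).  Isolated nodes retain all their heat (F block = 1).
    """
    if not 0.0 < beta <= 1.0:
        raise ValueError("beta must lie in (0, 1]")
    nodes = sorted(net.nodes)
    index = {g: i for i, g in enumerate(nodes)}
    n = len(nodes)
    F = np.zeros((n, n))
    for comp in nx.connected_components(net):
        idx = np.array(sorted(index[g] for g in comp))
        if len(idx) == 1:
            F[idx[0], idx[0]] = 1.0
            continue
        sub = [nodes[i] for i in idx]
        A = nx.to_numpy_array(net, nodelist=sub)
        W = A / A.sum(axis=0, keepdims=True)
        M = np.eye(len(idx)) - (1.0 - beta) * W
        F[np.ix_(idx, idx)] = beta * np.linalg.solve(M, np.eye(len(idx)))
    return F, nodes


def exchanged_heat(F: np.ndarray, nodes: list[str], heats: dict[str, GeneHeat] | dict[str, float]) -> np.ndarray:
    """E_ij = F_ij h_j; genes absent from ``heats`` are cold (h = 0)."""
    h = np.zeros(len(nodes))
    for i, g in enumerate(nodes):
        gh = heats.get(g)
        if gh is None:
            continue
        h[i] = gh.score if isinstance(gh, GeneHeat) else float(gh)
    if np.any(h < 0):
        raise ValueError("heat scores must be nonnegative")
    return F * h[None, :]


def _strong_components(E: np.ndarray, delta: float) -> tuple[np.ndarray, int]:
    """SCC labels of the directed graph with arc j->i iff E_ij > delta."""
    mask = E > delta
    np.fill_diagonal(mask, False)
    # arc j -> i when E_ij > delta: adjacency[from, to] = mask.T
    graph = csr_matrix(mask.T)
    n_comp, labels = connected_components(graph, directed=True, connection="strong")
    return labels, n_comp


def extract_subnetworks(
    E: np.ndarray,
    nodes: list[str],
    net: nx.Graph,
    delta: float,
    min_size: int = 4,
    network_label: str = "",
) -> list[Subnetwork]:
    """Strongly connected components of the delta-thresholded exchanged heat.

    Components with at least ``min_size`` genes are returned with their
    induced PPI edges, largest first (ties by lexicographic gene list).
    """
    if delta <= 0:
        raise ValueError("delta must be positive")
    labels, n_comp = _strong_components(E, delta)
    subs = []
    for c in range(n_comp):
        members = [nodes[i] for i in np.flatnonzero(labels == c)]
        if len(members) < min_size:
            continue
        induced = [tuple(sorted(e)) for e in net.subgraph(members).edges]
        subs.append(Subnetwork(genes=frozenset(members), induced_edges=sorted(induced), network_label=network_label))
    subs.sort(key=lambda s: (-s.size, sorted(s.genes)))
    for i, s in enumerate(subs):
        s.subnetwork_id = f"{network_label or 'net'}{i + 1}"
    return subs


def _min_delta_for_cap(E: np.ndarray, cap: int) -> float:
    """Smallest threshold (among E's values) keeping the largest SCC below cap."""
    vals = E.copy()
    np.fill_diagonal(vals, 0.0)
    cand = np.unique(vals[vals > 0])
    if cand.size == 0:
        raise ValueError("exchanged-heat matrix is all zero")
    # largest SCC size is non-increasing in delta -> binary search
    lo, hi = 0, cand.size - 1

    def max_scc(delta: float) -> int:
        labels, n_comp = _strong_components(E, delta)
        return int(np.bincount(labels, minlength=n_comp).max())

    if max_scc(cand[hi]) >= cap:
        return float(cand[hi])
    while lo < hi:
        mid = (lo + hi) // 2
        if max_scc(cand[mid]) < cap:
            hi = mid
        else:
            lo = mid + 1
    return float(cand[lo])


def auto_delta(E_permuted: list[np.ndarray], max_size_cap: int = 10) -> float:
    """Median, over permuted-heat E matrices, of the smallest delta that
    keeps the largest strongly connected component below ``max_size_cap``.

    Larger caps give smaller (or equal) deltas.  Requires a finite cap of
    at least 2 and a non-degenerate ensemble.
    """
    if not np.isfinite(max_size_cap) or max_size_cap < 2:
        raise ValueError("max_size_cap must be a finite integer >= 2")
    if len(E_permuted) == 0:
        raise ValueError("need at least one permuted E matrix")
    deltas = [_min_delta_for_cap(E, int(max_size_cap)) for E in E_permuted]
    return float(np.median(deltas))


def permuted_heat_ensemble(
    F: np.ndarray,
    nodes: list[str],
    heats: dict[str, GeneHeat] | dict[str, float],
    n_perm: int,
    rng: np.random.Generator,
) -> list[np.ndarray]:
    """E matrices for uniform permutations of the heat vector over nodes."""
    E0 = exchanged_heat(F, nodes, heats)
    h = E0.sum(axis=0)  # column sums recover h since F is column stochastic
    out = []
    for _ in range(n_perm):
        out.append(F * rng.permutation(h)[None, :])
    return out


def discovery_significance(
    F: np.ndarray,
    nodes: list[str],
    net: nx.Graph,
    heats: dict[str, GeneHeat] | dict[str, float],
    subnetworks: list[Subnetwork],
    delta: float,
    n_perm: int,
    rng: np.random.Generator,
    min_size: int = 4,
) -> dict[int, float]:
    """Empirical p-value per subnetwork size class under heat permutation.

    For each observed size s, p(s) is the add-one fraction of permutations
    producing at least as many components of size >= s as observed.
    Subnetworks are annotated in place; the size -> p map is returned.
    """
    if n_perm < 20:
        raise ValueError("need at least 20 permutations")
    sizes = sorted({s.size for s in subnetworks})
    if not sizes:
        return {}
    obs_counts = {s: sum(1 for sub in subnetworks if sub.size >= s) for s in sizes}
    exceed = {s: 0 for s in sizes}
    for E_perm in permuted_heat_ensemble(F, nodes, heats, n_perm, rng):
        perm_subs = extract_subnetworks(E_perm, nodes, net, delta, min_size)
        perm_sizes = np.array([p.size for p in perm_subs], dtype=int)
        for s in sizes:
            if (perm_sizes >= s).sum() >= obs_counts[s]:
                exceed[s] += 1
    pvals = {s: (exceed[s] + 1) / (n_perm + 1) for s in sizes}
    for sub in subnetworks:
        sub.size_class_p = pvals[sub.size]
    return pvals


def jaccard_shared(subs_a: list[Subnetwork], subs_b: list[Subnetwork], threshold: float = 0.5) -> list[tuple[str, str, float]]:
    """Pairs of subnetworks from two networks sharing >= threshold Jaccard gene overlap."""
    shared = []
    for a in subs_a:
        for b in subs_b:
            j = len(a.genes & b.genes) / len(a.genes | b.genes)
            if j >= threshold:
                shared.append((a.subnetwork_id, b.subnetwork_id, j))
    return shared
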