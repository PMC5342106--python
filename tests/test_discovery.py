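import itertools

import networkx as nx
import numpy as np
import pytest

from netprog._rng import substream
from netprog.discovery import (
    auto_delta,
    discovery_significance,
    exchanged_heat,
    extract_subnetworks,
    insulated_diffusion,
    permuted_heat_ensemble,
    _strong_components,
)


def _random_graph(rng, n, p=0.4):
    g = nx.Graph()
    g.add_nodes_from(f"N{i}" for i in range(n))
    for i, j in itertools.combinations(range(n), 2):
        if rng.random() < p:
            g.add_edge(f"N{i}", f"N{j}")
    return g


def test_beta_one_gives_identity():
    g = _random_graph(np.random.default_rng(0), 6)
    F, nodes = insulated_diffusion(g, 1.0)
    np.testing.assert_allclose(F, np.eye(len(nodes)), atol=1e-12)


def test_two_node_edge_closed_form():
    g = nx.Graph([("A", "B")])
    F, nodes = insulated_diffusion(g, 0.5)
    np.testing.assert_allclose(F, [[2 / 3, 1 / 3], [1 / 3, 2 / 3]], atol=1e-12)


def test_invalid_beta_rejected():
    g = nx.Graph([("A", "B")])
    for beta in (0.0, -0.1, 1.5):
        with pytest.raises(ValueError):
            insulated_diffusion(g, beta)


def test_matches_dense_inverse_and_column_sums():
    """Linear-solve F equals the dense closed form on random graphs; each
    column sums to 1 (heat conservation)."""
    rng = np.random.default_rng(1)
    for _ in range(40):
        n = int(rng.integers(2, 9))
        g = _random_graph(rng, n, p=0.5)
        beta = float(rng.uniform(0.1, 0.9))
        F, nodes = insulated_diffusion(g, beta)
        A = nx.to_numpy_array(g, nodelist=nodes)
        deg = A.sum(axis=0)
        W = np.divide(A, deg, out=np.zeros_like(A), where=deg > 0)
        iso = deg == 0
        dense = beta * np.linalg.inv(np.eye(n) - (1 - beta) * W)
        if iso.any():
            dense[np.ix_(iso, iso)] = np.eye(int(iso.sum()))
        np.testing.assert_allclose(F, dense, atol=1e-10)
        np.testing.assert_allclose(F.sum(axis=0), 1.0, atol=1e-8)


def test_exchanged_heat_conservation_and_support():
    rng = np.random.default_rng(2)
    g = _random_graph(rng, 7, p=0.6)
    F, nodes = insulated_diffusion(g, 0.4)
    heats = {n: float(rng.uniform(0, 5)) for n in nodes}
    E = exchanged_heat(F, nodes, heats)
    h = np.array([heats[n] for n in nodes])
    np.testing.assert_allclose(E.sum(axis=0), h, atol=1e-8)
    # all-zero heat -> zero E; single hot gene -> single nonzero column
    assert exchanged_heat(F, nodes, {}).sum() == 0.0
    E1 = exchanged_heat(F, nodes, {nodes[2]: 3.0})
    assert (E1[:, [i for i in range(len(nodes)) if i != 2]] == 0).all()
    with pytest.raises(ValueError, match="nonnegative"):
        exchanged_heat(F, nodes, {nodes[0]: -1.0})


def _brute_scc(E, delta):
    """Reachability-based strongly-connected-components oracle."""
    n = E.shape[0]
    adj = (E > delta)
    np.fill_diagonal(adj, False)
    # arc j -> i iff E_ij > delta
    reach = [set() for _ in range(n)]
    for j in range(n):
        stack, seen = [j], {j}
        while stack:
            u = stack.pop()
            for v in np.flatnonzero(adj[:, u]):
                if v not in seen:
                    seen.add(v)
                    stack.append(v)
        reach[j] = seen
    comp = {}
    for i in range(n):
        comp[i] = frozenset(k for k in range(n) if i in reach[k] and k in reach[i])
    return set(comp.values())


def test_scc_extraction_matches_reachability_oracle():
    rng = np.random.default_rng(3)
    for _ in range(60):
        n = int(rng.integers(2, 9))
        E = rng.uniform(0, 1, (n, n)) * (rng.random((n, n)) < 0.5)
        delta = float(rng.uniform(0.05, 0.8))
        labels, n_comp = _strong_components(E, delta)
        got = {frozenset(np.flatnonzero(labels == c)) for c in range(n_comp)}
        assert got == _brute_scc(E, delta)


def test_delta_above_max_gives_no_subnetworks():
    g = _random_graph(np.random.default_rng(4), 8, p=0.6)
    F, nodes = insulated_diffusion(g, 0.4)
    E = exchanged_heat(F, nodes, {n: 1.0 for n in nodes})
    assert extract_subnetworks(E, nodes, g, float(E.max()) + 1.0, 2) == []


def test_min_size_filters_components():
    g = nx.complete_graph(4)
    g = nx.relabel_nodes(g, {i: f"N{i}" for i in range(4)})
    F, nodes = insulated_diffusion(g, 0.4)
    E = exchanged_heat(F, nodes, {n: 10.0 for n in nodes})
    assert extract_subnetworks(E, nodes, g, float(E[E > 0].min()) / 2, min_size=5) == []
    subs = extract_subnetworks(E, nodes, g, float(E[E > 0].min()) / 2, min_size=4)
    assert len(subs) == 1 and subs[0].size == 4
    assert len(subs[0].induced_edges) == 6


def test_subnetworks_shrink_as_delta_grows():
    rng = np.random.default_rng(5)
    g = _random_graph(rng, 12, p=0.4)
    F, nodes = insulated_diffusion(g, 0.4)
    E = exchanged_heat(F, nodes, {n: float(rng.uniform(0, 8)) for n in nodes})
    prev_nodes = None
    for delta in (0.01, 0.05, 0.2, 0.8):
        subs = extract_subnetworks(E, nodes, g, delta, 2)
        covered = set().union(*[s.genes for s in subs]) if subs else set()
        if prev_nodes is not None:
            assert covered <= prev_nodes
        prev_nodes = covered


def test_auto_delta_degenerate_equal_entries():
    n = 5
    E = np.full((n, n), 0.7)
    assert auto_delta([E], max_size_cap=2) == pytest.approx(0.7)


def test_auto_delta_guards():
    with pytest.raises(ValueError):
        auto_delta([], 10)
    with pytest.raises(ValueError):
        auto_delta([np.ones((3, 3))], np.inf)
    with pytest.raises(ValueError, match="all zero"):
        auto_delta([np.zeros((3, 3))], 5)


def test_auto_delta_monotone_in_cap():
    rng = np.random.default_rng(6)
    ens = [rng.uniform(0, 1, (15, 15)) for _ in range(10)]
    deltas = [auto_delta(ens, cap) for cap in (2, 4, 8, 12)]
    assert all(a >= b for a, b in zip(deltas, deltas[1:]))


def test_planted_hot_clique_recovered_on_cold_background():
    """A hot 6-clique in a cold 30-node graph is returned for mid-range delta."""
    rng = np.random.default_rng(7)
    g = _random_graph(rng, 30, p=0.08)
    clique = [f"N{i}" for i in range(6)]
    g.add_edges_from(itertools.combinations(clique, 2))
    F, nodes = insulated_diffusion(g, 0.4)
    heats = {n: (50.0 if n in clique else 0.0) for n in nodes}
    E = exchanged_heat(F, nodes, heats)
    ens = permuted_heat_ensemble(F, nodes, heats, 10, substream(7, "auto_delta"))
    delta = auto_delta(ens, 5)
    subs = extract_subnetworks(E, nodes, g, delta, 4)
    assert subs, "no subnetwork found"
    best = max(len(s.genes & set(clique)) / len(s.genes | set(clique)) for s in subs)
    assert best >= 0.5


def test_significance_pvalues_have_addone_granularity():
    rng = np.random.default_rng(8)
    g = _random_graph(rng, 25, p=0.12)
    clique = [f"N{i}" for i in range(5)]
    g.add_edges_from(itertools.combinations(clique, 2))
    F, nodes = insulated_diffusion(g, 0.4)
    heats = {n: (40.0 if n in clique else float(rng.uniform(0, 3))) for n in nodes}
    E = exchanged_heat(F, nodes, heats)
    subs = extract_subnetworks(E, nodes, g, 0.5, 4)
    assert subs
    n_perm = 20
    pvals = discovery_significance(F, nodes, g, heats, subs, 0.5, n_perm, substream(8, "sig"))
    for p in pvals.values():
        assert p * (n_perm + 1) == pytest.approx(round(p * (n_perm + 1)))
        assert 0 < p <= 1
    for s in subs:
        assert s.size_class_p == pvals[s.size]
    with pytest.raises(ValueError, match="20"):
        discovery_significance(F, nodes, g, heats, subs, 0.5, 5, substream(8, "x"))


def test_hot_module_significant_under_permutation():
    rng = np.random.default_rng(9)
    g = _random_graph(rng, 40, p=0.05)
    clique = [f"N{i}" for i in range(6)]
    g.add_edges_from(itertools.combinations(clique, 2))
    F, nodes = insulated_diffusion(g, 0.4)
    heats = {n: (60.0 if n in clique else 0.0) for n in nodes}
    E = exchanged_heat(F, nodes, heats)
    subs = extract_subnetworks(E, nodes, g, 1.0, 4)
    assert subs
    pvals = discovery_significance(F, nodes, g, heats, subs, 1.0, 99, substream(9, "sig"))
    assert min(pvals.values()) <= 0.05
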