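"""Shared fixtures: small graphs, oscillator specs and brute-force oracles."""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np
import pytest

from megsw import BinaryGraph, ConnectivityMatrix, band_by_name


def brute_force_clustering(adj: np.ndarray) -> float:
    """Mean clustering by exhaustive triple enumeration (test oracle)."""
    n = adj.shape[0]
    cis = []
    for i in range(n):
        nbrs = [j for j in range(n) if adj[i, j]]
        k = len(nbrs)
        if k < 2:
            cis.append(0.0)
            continue
        links = sum(1 for a, b in itertools.combinations(nbrs, 2) if adj[a, b])
        cis.append(2.0 * links / (k * (k - 1)))
    return float(np.mean(cis))


def brute_force_path_length(adj: np.ndarray) -> float:
    """Mean finite shortest-path length by Floyd-Warshall (test oracle)."""
    n = adj.shape[0]
    D = np.full((n, n), np.inf)
    np.fill_diagonal(D, 0.0)
    D[adj > 0] = 1.0
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if D[i, k] + D[k, j] < D[i, j]:
                    D[i, j] = D[i, k] + D[k, j]
    mask = np.isfinite(D) & ~np.eye(n, dtype=bool)
    if not mask.any():
        raise ValueError("no finite pairs")
    return float(D[mask].mean())


def graph_battery(max_n: int = 8, n_random: int = 60, seed: int = 0) -> list[np.ndarray]:
    """Adjacency matrices covering special and random graphs up to max_n nodes,
    including disconnected cases."""
    mats = []
    for n in range(3, max_n + 1):
        mats.append(nx.to_numpy_array(nx.complete_graph(n), dtype=int))
        mats.append(nx.to_numpy_array(nx.path_graph(n), dtype=int))
        mats.append(nx.to_numpy_array(nx.star_graph(n - 1), dtype=int))
        mats.append(nx.to_numpy_array(nx.cycle_graph(n), dtype=int))
    # two disjoint K2 components, and K3 + isolated node
    two_k2 = np.zeros((4, 4), dtype=int)
    two_k2[0, 1] = two_k2[1, 0] = two_k2[2, 3] = two_k2[3, 2] = 1
    mats.append(two_k2)
    k3_iso = np.zeros((4, 4), dtype=int)
    k3_iso[:3, :3] = 1 - np.eye(3, dtype=int)
    mats.append(k3_iso)
    rng = np.random.default_rng(seed)
    made = 0
    while made < n_random:
        n = int(rng.integers(4, max_n + 1))
        p = float(rng.uniform(0.15, 0.9))
        g = nx.gnp_random_graph(n, p, seed=int(rng.integers(0, 2**31)))
        adj = nx.to_numpy_array(g, dtype=int)
        if adj.sum() == 0:
            continue
        mats.append(adj)
        made += 1
    return mats


@pytest.fixture(scope="session")
def small_graph_battery() -> list[np.ndarray]:
    return graph_battery()


@pytest.fixture
def random_connectivity_68() -> ConnectivityMatrix:
    rng = np.random.default_rng(7)
    w = rng.random((68, 68))
    w = np.triu(w, k=1)
    w = w + w.T
    return ConnectivityMatrix(weights=w * 0.999, band=band_by_name("alpha"))


@pytest.fixture
def path3() -> BinaryGraph:
    adj = np.zeros((3, 3), dtype=int)
    adj[0, 1] = adj[1, 0] = adj[1, 2] = adj[2, 1] = 1
    return BinaryGraph(adjacency=adj)
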