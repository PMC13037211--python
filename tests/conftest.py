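"""Shared fixtures: tiny hand-checkable graphs and independent oracles."""

from __future__ import annotations

import networkx as nx
import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from herbnet.network import InteractionNetwork

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def net_from_edges(edges: list[tuple[str, str]]) -> InteractionNetwork:
    g = nx.Graph()
    g.add_edges_from(edges)
    return InteractionNetwork(g)


@pytest.fixture
def path_net() -> InteractionNetwork:
    """The path graph A-B-C-D."""
    return net_from_edges([("A", "B"), ("B", "C"), ("C", "D")])


@pytest.fixture
def random_net_factory():
    """Seeded connected Erdos-Renyi-ish graphs with string node labels."""

    def make(n: int, p: float, seed: int) -> InteractionNetwork:
        rng = np.random.default_rng(seed)
        g = nx.Graph()
        g.add_nodes_from(f"n{i}" for i in range(n))
        for i in range(n):
            for j in range(i + 1, n):
                if rng.random() < p:
                    g.add_edge(f"n{i}", f"n{j}")
        # attach isolated nodes so the graph need not be connected but has edges
        if g.number_of_edges() == 0:
            g.add_edge("n0", "n1")
        return InteractionNetwork(g)

    return make


def floyd_warshall(net: InteractionNetwork) -> tuple[list[str], np.ndarray]:
    """Brute-force all-pairs shortest paths, independent of any BFS code."""
    order = sorted(net.graph.nodes)
    index = {n: i for i, n in enumerate(order)}
    n = len(order)
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)
    for a, b in net.graph.edges:
        dist[index[a], index[b]] = 1.0
        dist[index[b], index[a]] = 1.0
    for k in range(n):
        for i in range(n):
            for j in range(n):
                via = dist[i, k] + dist[k, j]
                if via < dist[i, j]:
                    dist[i, j] = via
    return order, dist


def rank_then_pearson(x, y) -> float:
    """Spearman oracle: midranks by hand, then Pearson correlation."""

    def midranks(v):
        v = np.asarray(v, dtype=float)
        order = np.argsort(v, kind="mergesort")
        ranks = np.empty(len(v))
        i = 0
        sorted_v = v[order]
        while i < len(v):
            j = i
            while j + 1 < len(v) and sorted_v[j + 1] == sorted_v[i]:
                j += 1
            ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
            i = j + 1
        return ranks

    rx, ry = midranks(x), midranks(y)
    return float(np.corrcoef(rx, ry)[0, 1])
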