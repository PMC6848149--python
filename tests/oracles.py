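"""Independent brute-force oracles for centrality and motif checks.

These deliberately avoid the code paths (and networkx calls) used by the
implementation: shortest paths come from a hand-rolled BFS, betweenness from
explicit enumeration of all geodesics, spectral quantities from dense
numpy/scipy decompositions. Only practical for tiny graphs.
"""

from __future__ import annotations

import itertools
from collections import deque

import networkx as nx
import numpy as np
import scipy.linalg


def bfs_distances(adj: dict, source) -> dict:
    dist = {source: 0}
    q = deque([source])
    while q:
        u = q.popleft()
        for v in adj[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                q.append(v)
    return dist


def all_shortest_paths(adj: dict, s, t) -> list[list]:
    """Every geodesic from s to t, by BFS layers + path enumeration."""
    dist = bfs_distances(adj, s)
    if t not in dist:
        return []
    paths = []

    def extend(path):
        u = path[-1]
        if u == t:
            paths.append(path)
            return
        for v in adj[u]:
            if dist.get(v) == dist[u] + 1 and dist[v] <= dist[t]:
                extend(path + [v])

    extend([s])
    return [p for p in paths if len(p) - 1 == dist[t]]


def closeness_oracle(G: nx.Graph, convention: str = "scaled") -> dict:
    adj = {n: set(G[n]) for n in G}
    n = G.number_of_nodes()
    out = {}
    for v in G:
        total = sum(d for u, d in bfs_distances(adj, v).items() if u != v)
        num = n if convention == "scaled" else n - 1
        out[v] = num / total if total else 0.0
    return out


def betweenness_oracle(G: nx.Graph, normalized: bool = False) -> dict:
    adj = {n: set(G[n]) for n in G}
    nodes = list(G)
    raw = dict.fromkeys(nodes, 0.0)
    for s, t in itertools.combinations(nodes, 2):
        paths = all_shortest_paths(adj, s, t)
        if not paths:
            continue
        for v in nodes:
            if v in (s, t):
                continue
            through = sum(1 for p in paths if v in p)
            raw[v] += through / len(paths)
    if normalized:
        n = len(nodes)
        m = (n - 1) * (n - 2) / 2
        return {v: c / m for v, c in raw.items()}
    return raw


def eigenvector_oracle(G: nx.Graph) -> dict:
    nodes = sorted(G)
    A = nx.to_numpy_array(G, nodelist=nodes)
    w, V = np.linalg.eigh(A)
    vec = np.abs(V[:, np.argmax(w)])
    vec /= vec.max()
    return dict(zip(nodes, vec))


def subgraph_oracle(G: nx.Graph) -> dict:
    nodes = sorted(G)
    A = nx.to_numpy_array(G, nodelist=nodes)
    return dict(zip(nodes, np.diag(scipy.linalg.expm(A))))


def triangles_oracle(G: nx.Graph) -> int:
    return sum(
        1
        for a, b, c in itertools.combinations(sorted(G), 3)
        if G.has_edge(a, b) and G.has_edge(b, c) and G.has_edge(a, c)
    )


def rich_club_oracle(G: nx.Graph, strict: bool = True) -> dict:
    degs = dict(G.degree())
    out = {}
    maxdeg = max(degs.values(), default=0)
    ks = range(0, maxdeg) if strict else range(1, maxdeg + 1)
    for k in ks:
        club = [n for n, d in degs.items() if (d > k if strict else d >= k)]
        if len(club) < 2:
            continue
        sub = G.subgraph(club)
        out[k] = 2 * sub.number_of_edges() / (len(club) * (len(club) - 1))
    return out


def random_connected_graph(rng: np.random.Generator, n_max: int = 7) -> nx.Graph:
    """Small random connected simple graph with string node IDs."""
    while True:
        n = int(rng.integers(3, n_max + 1))
        p = float(rng.uniform(0.3, 0.9))
        G = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
        if G.number_of_edges() and nx.is_connected(G):
            return nx.relabel_nodes(G, {i: f"v{i}" for i in G.nodes})
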