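"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive — pure-Python BFS, O(N^3) triple
enumeration, per-dyad loops, direct numerical likelihood maximisation —
and shares no code with the implementations it checks.
"""

from collections import deque
from itertools import combinations

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, xlogy


def bfs_distances(adjacency: dict, source):
    """Single-source shortest-path edge counts by breadth-first search."""
    dist = {source: 0}
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for v in adjacency[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                queue.append(v)
    return dist


def _adjacency(graph):
    return {u: set(graph.neighbors(u)) for u in graph.nodes}


def brute_mean_degree(graph) -> float:
    degrees = [len(list(graph.neighbors(u))) for u in graph.nodes]
    return sum(degrees) / len(degrees)


def brute_mean_distance(graph) -> float:
    adj = _adjacency(graph)
    total, pairs = 0, 0
    nodes = list(graph.nodes)
    for i, u in enumerate(nodes):
        dist = bfs_distances(adj, u)
        for v in nodes[i + 1 :]:
            if v in dist:
                total += dist[v]
                pairs += 1
    return total / pairs


def brute_transitivity(graph) -> float:
    """3 * triangles / connected triples by exhaustive enumeration."""
    adj = _adjacency(graph)
    nodes = list(graph.nodes)
    triples = closed = 0
    for centre in nodes:
        for a, b in combinations(adj[centre], 2):
            triples += 1
            if b in adj[a]:
                closed += 1
    return closed / triples


def incidence_projection(ties, patients, professionals):
    """Unipartite adjacency and weights via the incidence-matrix product.

    ``ties`` is an iterable of (patient, professional) pairs; returns
    (adjacency bool matrix, shared-patient count matrix) over sorted
    professionals.
    """
    pats = sorted(patients)
    pros = sorted(professionals)
    B = np.zeros((len(pros), len(pats)), dtype=int)
    pi = {p: k for k, p in enumerate(pats)}
    hi = {h: k for k, h in enumerate(pros)}
    for p, h in ties:
        B[hi[h], pi[p]] = 1
    W = B @ B.T
    np.fill_diagonal(W, 0)
    return W > 0, W, pros


def dyad_change_stats(u_attrs, v_attrs, columns):
    """Change statistics for one dyad from explicit column descriptors.

    ``columns`` is a list of tuples: ("edges",), ("nodefactor", attr,
    level) or ("nodematch", attr).
    """
    row = []
    for col in columns:
        if col[0] == "edges":
            row.append(1)
        elif col[0] == "nodefactor":
            _, attr, level = col
            row.append(int(u_attrs[attr] == level) + int(v_attrs[attr] == level))
        else:
            _, attr = col
            row.append(int(u_attrs[attr] == v_attrs[attr]))
    return row


def naive_dyad_table(graph, columns):
    """Per-dyad change-statistic rows and tie indicators by a double loop."""
    nodes = sorted(graph.nodes)
    rows, ties = [], []
    for u, v in combinations(nodes, 2):
        rows.append(dyad_change_stats(graph.nodes[u], graph.nodes[v], columns))
        ties.append(int(graph.has_edge(u, v)))
    return np.array(rows, dtype=float), np.array(ties, dtype=float)


def global_statistic(graph, column):
    """Whole-graph statistic for one column descriptor, by recount."""
    total = 0
    for u, v in graph.edges():
        total += dyad_change_stats(graph.nodes[u], graph.nodes[v], [column])[0]
    return total


def direct_mple(X, ties, absent):
    """Maximise the grouped dyad likelihood numerically (BFGS), starting
    from several points to avoid any path dependence."""

    def negll(theta):
        p = expit(X @ theta)
        return -float(np.sum(xlogy(ties, p) + xlogy(absent, 1.0 - p)))

    best = None
    for start in (np.zeros(X.shape[1]), np.full(X.shape[1], 0.5),
                  np.full(X.shape[1], -0.5)):
        res = minimize(negll, start, method="BFGS",
                       options={"gtol": 1e-12, "maxiter": 500})
        if best is None or res.fun < best.fun:
            best = res
    return best.x
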