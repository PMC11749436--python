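"""Descriptive network metrics for patient-sharing networks.

For each (sub-)network: number of edges, mean degree 2E/N, density
2E/(N(N-1)), mean geodesic distance over connected pairs, and global
transitivity 3·triangles / connected triples.  Metrics that are undefined
on a given graph (empty node set, no connected pairs, no triples) raise
:class:`UndefinedMetricError`; :func:`summarize` records them as missing
(NaN), never as zero.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Optional

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse.csgraph import connected_components, shortest_path

from .errors import UndefinedMetricError
from .network_build import known_municipalities, municipality_subnetwork
from .registry_io import VisitTable

#: Column order of the per-municipality metrics table.
METRIC_COLUMNS = (
    "n_nodes",
    "n_edges",
    "mean_degree",
    "density",
    "mean_distance",
    "transitivity",
)


@dataclasses.dataclass(frozen=True)
class NetworkMetrics:
    n_nodes: int
    n_edges: int
    mean_degree: float
    density: float
    mean_distance: float  # NaN when undefined
    transitivity: float  # NaN when undefined

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def mean_degree(net: nx.Graph) -> float:
    """Average number of contacts per professional, 2E/N."""
    n = net.number_of_nodes()
    if n == 0:
        raise UndefinedMetricError("mean degree undefined on an empty node set")
    return 2.0 * net.number_of_edges() / n


def density(net: nx.Graph) -> float:
    """Contacts divided by all possible contacts, 2E/(N(N-1))."""
    n = net.number_of_nodes()
    if n < 2:
        raise UndefinedMetricError("density undefined for fewer than 2 nodes")
    return 2.0 * net.number_of_edges() / (n * (n - 1))


def mean_distance(net: nx.Graph) -> float:
    """Mean geodesic (shortest-path edge count) over connected pairs.

    Pairs in different components are excluded; with no connected pair the
    metric is undefined.
    """
    n = net.number_of_nodes()
    if n < 2 or net.number_of_edges() == 0:
        raise UndefinedMetricError("mean distance undefined without a connected pair")
    nodes = list(net.nodes)
    adj = nx.to_scipy_sparse_array(net, nodelist=nodes, weight=None, format="csr")
    n_comp, labels = connected_components(csgraph=adj, directed=False)
    total = 0.0
    pairs = 0
    for comp in range(n_comp):
        idx = np.flatnonzero(labels == comp)
        if len(idx) < 2:
            continue
        sub = adj[idx][:, idx]
        dist = shortest_path(sub, method="D", directed=False, unweighted=True)
        iu = np.triu_indices(len(idx), 1)
        d = dist[iu]
        total += float(d.sum())
        pairs += d.size
    if pairs == 0:
        raise UndefinedMetricError("mean distance undefined without a connected pair")
    return total / pairs


def transitivity(net: nx.Graph) -> float:
    """Global transitivity: 3 × triangles / connected triples."""
    n_triples = sum(d * (d - 1) // 2 for _, d in net.degree())
    if n_triples == 0:
        raise UndefinedMetricError("transitivity undefined without connected triples")
    return nx.transitivity(net)


def summarize(net: nx.Graph) -> NetworkMetrics:
    """All Table-style metrics for one network; undefined entries are NaN."""
    n = net.number_of_nodes()
    e = net.number_of_edges()

    def _try(fn):
        try:
            return fn(net)
        except UndefinedMetricError:
            return math.nan

    return NetworkMetrics(
        n_nodes=n,
        n_edges=e,
        mean_degree=_try(mean_degree),
        density=_try(density),
        mean_distance=_try(mean_distance),
        transitivity=_try(transitivity),
    )


def summarize_by_municipality(
    table: VisitTable, municipalities: Optional[list[str]] = None
) -> pd.DataFrame:
    """Metrics table with one row per municipality sub-network."""
    rows = {}
    for m in municipalities or known_municipalities(table):
        rows[m] = summarize(municipality_subnetwork(table, m)).to_dict()
    out = pd.DataFrame.from_dict(rows, orient="index", columns=list(METRIC_COLUMNS))
    out.index.name = "municipality"
    return out
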