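"""Bipartite patient-professional graph and its unipartite projection.

Visits define a two-mode (bipartite) graph: patients on one side,
professionals on the other, a tie whenever a patient visited a
professional, weighted by the number of visits.  The one-mode
patient-sharing network connects two professionals iff at least one
patient visited both; the edge weight counts the distinct shared
patients.  The projection is the off-diagonal support of B·Bᵀ for the
professional-by-patient incidence matrix B — no transitive closure.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
from collections import Counter
from itertools import combinations
from typing import Optional

import networkx as nx
import pandas as pd

from .errors import ConfigError
from .registry_io import VisitTable

#: Node-key prefixes keeping the two modes disjoint inside one nx.Graph.
_PATIENT = "patient"
_PROFESSIONAL = "professional"


@dataclasses.dataclass
class BipartiteGraph:
    """Two-mode patient-professional graph with visit-count tie weights."""

    graph: nx.Graph
    patient_nodes: frozenset[str]
    professional_nodes: frozenset[str]

    @property
    def n_ties(self) -> int:
        return self.graph.number_of_edges()

    def ties(self) -> set[tuple[str, str]]:
        """The (patient_id, professional_id) pairs with at least one visit."""
        return {
            (u[1], v[1]) if u[0] == _PATIENT else (v[1], u[1])
            for u, v in self.graph.edges()
        }

    def tie_weight(self, patient_id: str, professional_id: str) -> int:
        return self.graph[(_PATIENT, patient_id)][(_PROFESSIONAL, professional_id)][
            "visits"
        ]


def build_bipartite(table: VisitTable) -> BipartiteGraph:
    """Build the two-mode graph: one tie per (patient, professional) pair,
    weighted by the number of visits between them."""
    g = nx.Graph()
    counts = table.df.groupby(["patient_id", "professional_id"]).size()
    patients = frozenset(table.df["patient_id"].unique())
    professionals = frozenset(
        table.df.loc[table.df["professional_id"] != "", "professional_id"].unique()
    )
    for p in patients:
        g.add_node((_PATIENT, p), bipartite=0)
    for h in professionals:
        g.add_node((_PROFESSIONAL, h), bipartite=1)
    for (p, h), n in counts.items():
        if h == "":
            continue
        g.add_edge((_PATIENT, p), (_PROFESSIONAL, h), visits=int(n))
    return BipartiteGraph(g, patients, professionals)


def project_unipartite(bg: BipartiteGraph) -> nx.Graph:
    """Project to the patient-sharing network over professionals.

    Edge (x, y) present iff some patient is tied to both x and y; the
    ``shared_patients`` weight is the number of such distinct patients.
    Professionals with no shared patients remain as isolated nodes.
    """
    shared: Counter[tuple[str, str]] = Counter()
    for p in bg.patient_nodes:
        node = (_PATIENT, p)
        if node not in bg.graph:
            continue
        pros = sorted(h for _, h in bg.graph.neighbors(node))
        for x, y in combinations(pros, 2):
            shared[(x, y)] += 1
    net = nx.Graph()
    net.add_nodes_from(sorted(bg.professional_nodes))
    for (x, y), w in shared.items():
        net.add_edge(x, y, shared_patients=w)
    return net


def attach_attributes(net: nx.Graph, attrs: pd.DataFrame) -> nx.Graph:
    """Set municipality/occupation/service node attributes from a table
    indexed by professional_id (in place; returns the graph)."""
    missing = [n for n in net.nodes if n not in attrs.index]
    if missing:
        raise ConfigError(
            f"{len(missing)} network node(s) lack attribute rows, e.g. {missing[:3]}"
        )
    for n in net.nodes:
        row = attrs.loc[n]
        for col in attrs.columns:
            net.nodes[n][col] = row[col]
    return net


def patient_sharing_network(
    table: VisitTable, attrs: Optional[pd.DataFrame] = None
) -> nx.Graph:
    """Convenience: bipartite build + projection (+ attribute attachment)."""
    net = project_unipartite(build_bipartite(table))
    if attrs is not None:
        attach_attributes(net, attrs)
    return net


def restrict_time_window(table: VisitTable, window_days: int) -> VisitTable:
    """Keep, per patient, only visits within ``window_days`` of their first.

    Used for the sensitivity analysis that restricts patient sharing to a
    3-month (90-day) span starting at each patient's first appointment of
    the study year.  The caller must re-apply the uninformative-patient
    filters before projecting.
    """
    if window_days <= 0:
        raise ConfigError(f"window_days must be positive, got {window_days}")
    df = table.df
    first = df.groupby("patient_id")["date"].transform("min")
    keep = df["date"] <= first + pd.Timedelta(days=window_days)
    out = VisitTable(df[keep].reset_index(drop=True), list(table.provenance),
                     dialect=table.dialect)
    out.log(f"restrict_time_window({window_days} days): {len(out)} visits kept")
    return out


def known_municipalities(table: VisitTable) -> list[str]:
    return sorted(table.df["municipality"].unique())


def municipality_subnetwork(table: VisitTable, municipality: str) -> nx.Graph:
    """Patient-sharing network of the visits occurring in one municipality.

    Built from the visits located in the municipality, not from the unique
    post-assignment attributes, so a professional with visits in several
    municipalities appears in each of those sub-networks.
    """
    known = known_municipalities(table)
    if municipality not in known:
        raise ConfigError(
            f"unknown municipality {municipality!r}; known codes: {known}"
        )
    sub = VisitTable(
        table.df[table.df["municipality"] == municipality].reset_index(drop=True),
        dialect=table.dialect,
    )
    return patient_sharing_network(sub)
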