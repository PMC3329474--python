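"""Time-decayed directed network snapshots.

The notification network at a query date is a directed weighted graph whose
nodes are countries and whose edges point detector -> transgressor.  Each
notification contributes a weight that starts at 1 on the day it is logged
and decays exponentially with a half-life of 180 days, so old reports fade
rather than vanish; parallel notifications between the same pair are summed
into a single edge weight.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date as Date
from pathlib import Path
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .notifications import NotificationLog


@dataclass(frozen=True)
class DecayParams:
    """Exponential decay with a configurable half-life (days)."""

    half_life_days: float = 180.0

    def __post_init__(self) -> None:
        if not self.half_life_days > 0:
            raise ValueError("half_life_days must be positive")


DEFAULT_DECAY = DecayParams()


def decay_weight(age_days: float, params: DecayParams = DEFAULT_DECAY) -> float:
    """Contribution of a notification ``age_days`` after logging.

    Returns ``2 ** (-age_days / half_life_days)``: 1 at age 0, exactly 1/2
    at one half-life, strictly decreasing and never zero.  Negative ages are
    rejected; records dated after the query date are excluded upstream, not
    extrapolated.
    """
    if age_days < 0:
        raise ValueError(f"age_days must be non-negative, got {age_days}")
    return 2.0 ** (-age_days / params.half_life_days)


class EmptySnapshotError(ValueError):
    """No notification on or before the requested query date."""


@dataclass
class Snapshot:
    """Directed weighted notification network at one query date."""

    query_date: Date
    nodes: set[str]
    edges: dict[tuple[str, str], float]
    params: DecayParams = DEFAULT_DECAY
    filters_applied: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for (u, v), w in self.edges.items():
            if w <= 0:
                raise ValueError(f"edge {u}->{v} has non-positive weight {w}")
            if u not in self.nodes or v not in self.nodes:
                raise ValueError(f"edge endpoint of {u}->{v} missing from nodes")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def sorted_nodes(self) -> list[str]:
        """Node labels in the deterministic (lexicographic) order used by
        every matrix computation and export."""
        return sorted(self.nodes)

    def weight_matrix(self) -> np.ndarray:
        """Dense adjacency ``W[i, j]`` = weight of edge i -> j, rows/cols in
        ``sorted_nodes`` order."""
        order = {c: i for i, c in enumerate(self.sorted_nodes())}
        W = np.zeros((len(order), len(order)))
        for (u, v), w in self.edges.items():
            W[order[u], order[v]] = w
        return W

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.sorted_nodes())
        for (u, v), w in sorted(self.edges.items()):
            g.add_edge(u, v, weight=w)
        g.graph["query_date"] = self.query_date.isoformat()
        g.graph["half_life_days"] = self.params.half_life_days
        for key, val in self.filters_applied.items():
            g.graph[f"filter_{key}"] = str(val)
        return g

    def undirected_projection(self, weighted: bool = True) -> nx.Graph:
        """Undirected view with opposite-direction weights summed."""
        g = nx.Graph()
        g.add_nodes_from(self.sorted_nodes())
        for (u, v), w in sorted(self.edges.items()):
            if g.has_edge(u, v):
                g[u][v]["weight"] += w if weighted else 0
            else:
                g.add_edge(u, v, weight=w if weighted else 1)
        return g


def build_snapshot(
    log: NotificationLog,
    query_date: Date,
    params: DecayParams = DEFAULT_DECAY,
    min_weight: float = 0.0,
    filters_applied: Mapping | None = None,
) -> Snapshot:
    """Aggregate a log into the decayed network at ``query_date``.

    Notifications dated on or before the query date contribute
    ``decay_weight(query_date - date)``; later ones are ignored.  The edge
    weight for a (detector, transgressor) pair is the sum of its
    notifications' contributions; edges below ``min_weight`` are dropped
    (their endpoints remain as nodes).  Age is measured in whole days.
    """
    if min_weight < 0:
        raise ValueError("min_weight must be >= 0")
    weights: dict[tuple[str, str], float] = {}
    nodes: set[str] = set()
    for rec in log:
        age = (query_date - rec.date).days
        if age < 0:
            continue
        nodes.add(rec.detector)
        nodes.add(rec.transgressor)
        key = (rec.detector, rec.transgressor)
        weights[key] = weights.get(key, 0.0) + decay_weight(age, params)
    if not nodes:
        raise EmptySnapshotError(
            f"empty snapshot: no notification on or before {query_date.isoformat()}"
        )
    edges = {k: w for k, w in weights.items() if w >= min_weight and w > 0}
    return Snapshot(
        query_date=query_date,
        nodes=nodes,
        edges=edges,
        params=params,
        filters_applied=dict(filters_applied or {}),
    )


def reverse(snapshot: Snapshot) -> Snapshot:
    """Same nodes and weights with every edge direction flipped.

    The detector index is the transgressor-index computation run on this
    reversed orientation, so being the *source* of many reports becomes the
    rewarded role."""
    return Snapshot(
        query_date=snapshot.query_date,
        nodes=set(snapshot.nodes),
        edges={(v, u): w for (u, v), w in snapshot.edges.items()},
        params=snapshot.params,
        filters_applied=dict(snapshot.filters_applied),
    )


def write_graphml(snapshot: Snapshot, path: str | Path) -> Path:
    path = Path(path)
    nx.write_graphml(snapshot.to_networkx(), path)
    return path


def write_edge_csv(snapshot: Snapshot, path: str | Path) -> Path:
    """Edge list ``source,target,weight`` in deterministic order."""
    path = Path(path)
    rows = [
        {"source": u, "target": v, "weight": w}
        for (u, v), w in sorted(snapshot.edges.items())
    ]
    pd.DataFrame(rows, columns=["source", "target", "weight"]).to_csv(
        path, index=False
    )
    return path


def half_life_ratio(age_days: float, params: DecayParams = DEFAULT_DECAY) -> float:
    """Ratio weight(age + half_life) / weight(age); exactly 1/2 for the
    exponential decay at any age — exposed for diagnostics."""
    return decay_weight(age_days + params.half_life_days, params) / decay_weight(
        age_days, params
    )
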