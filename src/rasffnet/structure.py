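"""Structural analytics on the undirected projection of a snapshot.

Beyond per-country indices, the notification network has mesoscale
structure: trading blocs show up as modules (clusters of countries that
report on each other much more than expected by chance), and the
core-periphery organisation shows up in the k-core decomposition.  Both
operate on the undirected projection where opposite-direction edge weights
are summed; the k-core additionally ignores weights, and self-report loops
are dropped before peeling.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx

from .decay import Snapshot


@dataclass(frozen=True)
class Partition:
    """Community assignment country -> community id with its modularity Q.

    Community ids are renumbered 0, 1, ... in order of each community's
    lexicographically smallest member, so identical partitions always get
    identical labels.
    """

    assignment: dict[str, int]
    modularity_q: float

    def communities(self) -> list[set[str]]:
        out: dict[int, set[str]] = {}
        for country, cid in self.assignment.items():
            out.setdefault(cid, set()).add(country)
        return [out[c] for c in sorted(out)]


def modularity(snapshot: Snapshot, assignment: dict[str, int]) -> float:
    """Newman weighted modularity of a community assignment.

    Q = sum over communities of (within-weight fraction) minus (expected
    fraction from the degree sequence); 0 for the one-community partition,
    negative when the split cuts more weight than chance would.
    """
    g = snapshot.undirected_projection(weighted=True)
    missing = sorted(set(g.nodes) - set(assignment))
    if missing:
        raise ValueError(f"assignment missing node(s): {', '.join(missing)}")
    groups: dict[int, set[str]] = {}
    for node in g.nodes:
        groups.setdefault(assignment[node], set()).add(node)
    return float(
        nx.community.modularity(g, list(groups.values()), weight="weight")
    )


def find_communities(
    snapshot: Snapshot, seed: int = 0, n_restarts: int = 8
) -> Partition:
    """Greedy multilevel (Louvain-style) modularity maximization.

    The heuristic is run ``n_restarts`` times with seeds derived from
    ``seed`` and the best-Q partition is kept — the multilevel heuristic is
    stochastic and restarts cheaply buy robustness on small graphs.  The
    returned Q is recomputed from the assignment via :func:`modularity`.
    """
    g = snapshot.undirected_projection(weighted=True)
    if g.number_of_edges() == 0:
        raise ValueError("community detection requires at least one edge")
    best: list[set[str]] | None = None
    best_q = -1.0
    for k in range(n_restarts):
        communities = nx.community.louvain_communities(
            g, weight="weight", seed=seed + k
        )
        q = nx.community.modularity(g, communities, weight="weight")
        if q > best_q:
            best, best_q = communities, q
    assert best is not None
    ordered = sorted(best, key=min)
    assignment = {node: cid for cid, com in enumerate(ordered) for node in com}
    return Partition(assignment=assignment, modularity_q=modularity(snapshot, assignment))


def k_core(snapshot: Snapshot) -> dict[str, int]:
    """Coreness of every country by iterative peeling.

    A country has coreness k if it survives in the maximal subgraph of
    minimum degree k.  Computed on the unweighted undirected projection with
    self-loops removed; isolated countries have coreness 0; an empty
    snapshot yields an empty map.
    """
    g = snapshot.undirected_projection(weighted=False)
    g.remove_edges_from(nx.selfloop_edges(g))
    if g.number_of_nodes() == 0:
        return {}
    return {node: int(c) for node, c in nx.core_number(g).items()}
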