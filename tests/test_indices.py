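"""PageRank and HITS transgressor/detector index engines."""

from datetime import date

import networkx as nx
import numpy as np
import pytest

from rasffnet import (
    ConvergenceError,
    IndexVector,
    Method,
    PageRankParams,
    Role,
    hits_indices,
    pagerank_indices,
    scale_for_report,
)
from rasffnet.indices import _hits_scores, _pagerank_scores
from conftest import snapshot_from_edges
from oracles import hits_eig, pagerank_linear_solve, random_digraph


def snapshot_from_matrix(W, labels=None):
    n = W.shape[0]
    labels = labels or [f"C{i:02d}" for i in range(n)]
    edges = {
        (labels[i], labels[j]): float(W[i, j])
        for i in range(n)
        for j in range(n)
        if W[i, j] > 0
    }
    return snapshot_from_edges(edges, extra_nodes=set(labels))


# ------------------------------------------------------------- pagerank
def test_pagerank_star_symmetry(star_snapshot):
    ti, di = pagerank_indices(star_snapshot)
    assert ti["IRN"] == pytest.approx(ti["CHN"]) == pytest.approx(ti["BRA"])
    assert ti["IRN"] > ti["DEU"]
    assert di["DEU"] > di["IRN"]  # sole reporter dominates the detector index
    assert sum(ti.scores.values()) == pytest.approx(1, abs=1e-12)
    assert sum(di.scores.values()) == pytest.approx(1, abs=1e-12)


def test_pagerank_matches_linear_solve_oracle():
    """Power iteration agrees with a dense linear-system solve on 100
    seeded random weighted digraphs of <= 8 nodes."""
    worst = 0.0
    for seed in range(100):
        W = random_digraph(np.random.default_rng(seed))
        snap = snapshot_from_matrix(W)
        ti, di = pagerank_indices(snap, PageRankParams(tol=1e-13))
        order = snap.sorted_nodes()
        expect_ti = pagerank_linear_solve(W, 0.85)
        expect_di = pagerank_linear_solve(W.T, 0.85)
        worst = max(
            worst,
            np.abs([ti[c] for c in order] - expect_ti).max(),
            np.abs([di[c] for c in order] - expect_di).max(),
        )
    assert worst < 1e-8


def test_pagerank_matches_networkx():
    W = random_digraph(np.random.default_rng(42))
    snap = snapshot_from_matrix(W)
    ti, _ = pagerank_indices(snap, PageRankParams(tol=1e-12))
    g = nx.DiGraph()
    g.add_nodes_from(snap.sorted_nodes())
    for (u, v), w in snap.edges.items():
        g.add_edge(u, v, weight=w)
    ref = nx.pagerank(g, alpha=0.85, tol=1e-12, max_iter=1000, weight="weight")
    for c in snap.sorted_nodes():
        assert ti[c] == pytest.approx(ref[c], abs=1e-8)


def test_pagerank_edgeless_snapshot_is_uniform():
    snap = snapshot_from_edges({}, extra_nodes={"DEU", "IRN", "CHN"})
    ti, di = pagerank_indices(snap)
    assert all(v == pytest.approx(1 / 3) for v in ti.scores.values())
    assert all(v == pytest.approx(1 / 3) for v in di.scores.values())


def test_pagerank_nonconvergence_reports_residual(star_snapshot):
    with pytest.raises(ConvergenceError, match="residual"):
        pagerank_indices(star_snapshot, PageRankParams(tol=1e-15, max_iter=2))


# ------------------------------------------------------------- HITS
def test_hits_star(star_snapshot):
    ti, di = hits_indices(star_snapshot)
    assert di["DEU"] == pytest.approx(1.0)
    assert di["IRN"] == di["CHN"] == di["BRA"] == pytest.approx(0.0)
    for c in ("IRN", "CHN", "BRA"):
        assert ti[c] == pytest.approx(1 / 3)
    assert ti["DEU"] == pytest.approx(0.0)


def test_hits_two_disjoint_stars_matches_eig_oracle():
    """Hub out-weights 2 vs 1: the heavier star carries the dominant
    mutual-reinforcement fixed point."""
    edges = {
        ("AAA", "BBB"): 2.0, ("AAA", "CCC"): 2.0,
        ("DDD", "EEE"): 1.0, ("DDD", "FFF"): 1.0,
    }
    snap = snapshot_from_edges(edges)
    ti, di = hits_indices(snap, tol=1e-12, max_iter=20000)
    order = snap.sorted_nodes()
    h, a = hits_eig(snap.weight_matrix())
    np.testing.assert_allclose([ti[c] for c in order], a, atol=1e-8)
    np.testing.assert_allclose([di[c] for c in order], h, atol=1e-8)
    assert di["AAA"] > di["DDD"]


def test_hits_matches_eig_oracle_on_random_digraphs():
    worst = 0.0
    for seed in range(100):
        W = random_digraph(np.random.default_rng(1000 + seed))
        snap = snapshot_from_matrix(W)
        ti, di = hits_indices(snap, tol=1e-13, max_iter=50000)
        order = snap.sorted_nodes()
        h, a = hits_eig(W)
        worst = max(
            worst,
            np.abs([ti[c] for c in order] - a).max(),
            np.abs([di[c] for c in order] - h).max(),
        )
    assert worst < 1e-8


def test_hits_matches_networkx():
    W = random_digraph(np.random.default_rng(7))
    snap = snapshot_from_matrix(W)
    ti, di = hits_indices(snap, tol=1e-12, max_iter=20000)
    g = snap.to_networkx()
    hubs, auth = nx.hits(g, max_iter=5000, tol=1e-12)
    for c in snap.sorted_nodes():
        assert ti[c] == pytest.approx(auth[c], abs=1e-6)
        assert di[c] == pytest.approx(hubs[c], abs=1e-6)


def test_hits_requires_an_edge():
    snap = snapshot_from_edges({}, extra_nodes={"DEU", "IRN"})
    with pytest.raises(ValueError, match="at least one edge"):
        hits_indices(snap)


def test_hits_and_pagerank_sums(star_snapshot):
    for ti, di in (pagerank_indices(star_snapshot), hits_indices(star_snapshot)):
        assert sum(ti.scores.values()) == pytest.approx(1, abs=1e-9)
        assert sum(di.scores.values()) == pytest.approx(1, abs=1e-9)


# ----------------------------------------------- coupling / independence
def test_hits_couples_roles_where_pagerank_does_not():
    """Raising the weight of a report into a high-TI country raises the
    reporter's HITS DI (mutual reinforcement) but does not change the
    reporters' PageRank DI ranking in the 2-hub configuration."""
    def build(w):
        return snapshot_from_edges(
            {("AAA", "XXX"): 1.0, ("AAA", "YYY"): 1.0, ("BBB", "XXX"): w}
        )

    _, di_hits_lo = hits_indices(build(1.0))
    _, di_hits_hi = hits_indices(build(3.0))
    assert di_hits_hi["BBB"] > di_hits_lo["BBB"]

    _, di_pr_lo = pagerank_indices(build(1.0))
    _, di_pr_hi = pagerank_indices(build(3.0))
    assert di_pr_lo["AAA"] > di_pr_lo["BBB"]
    assert di_pr_hi["AAA"] > di_pr_hi["BBB"]  # rank order preserved


def test_permutation_equivariance(star_snapshot):
    relabel = {"DEU": "FRA", "IRN": "TUR", "CHN": "IND", "BRA": "ARG"}
    permuted = snapshot_from_edges(
        {(relabel[u], relabel[v]): w for (u, v), w in star_snapshot.edges.items()}
    )
    for engine in (pagerank_indices, hits_indices):
        ti0, _ = engine(star_snapshot)
        ti1, _ = engine(permuted)
        for old, new in relabel.items():
            assert ti1[new] == pytest.approx(ti0[old], abs=1e-12)


def test_scale_invariance():
    W = random_digraph(np.random.default_rng(5))
    snap1 = snapshot_from_matrix(W)
    snap2 = snapshot_from_matrix(7.3 * W)
    for engine, kw in ((pagerank_indices, {}), (hits_indices, {"max_iter": 20000})):
        ti1, di1 = engine(snap1, **kw)
        ti2, di2 = engine(snap2, **kw)
        for c in snap1.sorted_nodes():
            assert ti1[c] == pytest.approx(ti2[c], abs=1e-9)
            assert di1[c] == pytest.approx(di2[c], abs=1e-9)


# ------------------------------------------------------------- reporting
def test_scale_for_report(star_snapshot):
    ti, _ = pagerank_indices(star_snapshot)
    scaled = scale_for_report(ti)
    assert sum(scaled.values()) == pytest.approx(1000)
    assert scaled["IRN"] == pytest.approx(ti["IRN"] * 1000)
    assert sum(ti.scores.values()) == pytest.approx(1)  # original untouched

    half = IndexVector(Method.PAGERANK, Role.TI, date(2008, 1, 1),
                       {"AAA": 0.5, "BBB": 0.5})
    assert scale_for_report(half)["AAA"] == pytest.approx(500)
    unit = IndexVector(Method.PAGERANK, Role.TI, date(2008, 1, 1),
                       {"AAA": 0.5, "BBB": 0.5}, report_scale=1.0)
    assert scale_for_report(unit) == pytest.approx(unit.scores)


def test_index_vector_validates():
    with pytest.raises(ValueError, match="sum to 1"):
        IndexVector(Method.PAGERANK, Role.TI, date(2008, 1, 1), {"AAA": 0.7})
    ok = IndexVector(Method.HITS, Role.DI, date(2008, 1, 1), {"AAA": 1.0})
    assert ok.top() == [("AAA", 1.0)]
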