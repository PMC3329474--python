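"""Independent oracles used to check the package's engines.

Each oracle takes a different computational route than the implementation
it validates: PageRank via a dense linear solve instead of power iteration,
HITS via symmetric eigendecomposition instead of mutual-reinforcement
iteration, modularity optima via exhaustive set-partition search instead of
the multilevel heuristic, and coreness via literal min-degree peeling.
"""

from __future__ import annotations

import numpy as np
import scipy.linalg


def pagerank_linear_solve(W: np.ndarray, damping: float) -> np.ndarray:
    """Stationary PageRank vector from the dense linear system
    (I - d M) x = (1-d)/n * 1, dangling columns uniform."""
    n = W.shape[0]
    out = W.sum(axis=1)
    dangling = out == 0
    P = np.divide(W, np.where(dangling, 1.0, out)[:, None])
    P[dangling] = 1.0 / n
    M = P.T
    x = np.linalg.solve(np.eye(n) - damping * M, np.full(n, (1 - damping) / n))
    return x / x.sum()


def hits_eig(W: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(hub, authority) from the principal eigenvector of W^T W.

    The authority vector is the dominant eigenvector of the symmetric PSD
    matrix W^T W; the hub vector is its image under W.  Both L1-normalized.
    """
    vals, vecs = scipy.linalg.eigh(W.T @ W)
    a = np.abs(vecs[:, -1])
    h = W @ a
    return h / h.sum(), a / a.sum()


def hits_power_naive(W: np.ndarray, n_iter: int = 100000, tol: float = 1e-15):
    """HITS by literal alternating matrix iteration with L1 renormalization,
    run to a much tighter fixed point than the implementation under test."""
    n = W.shape[0]
    h = np.full(n, 1.0 / n)
    a = np.zeros(n)
    for _ in range(n_iter):
        a_new = W.T @ h
        a_new /= a_new.sum()
        h_new = W @ a_new
        h_new /= h_new.sum()
        done = np.abs(a_new - a).max() < tol and np.abs(h_new - h).max() < tol
        a, h = a_new, h_new
        if done:
            break
    return h, a


def set_partitions(n: int):
    """All partitions of {0..n-1} as restricted-growth label arrays."""
    labels = np.zeros(n, dtype=int)

    def rec(i: int, maxlabel: int):
        if i == n:
            yield labels.copy()
            return
        for lab in range(maxlabel + 1):
            labels[i] = lab
            yield from rec(i + 1, max(maxlabel, lab + 1))

    yield from rec(1, 1) if n > 0 else iter(())


def modularity_from_matrix(W_sym: np.ndarray, labels: np.ndarray) -> float:
    """Newman modularity for a symmetric weight matrix (no self-loops)."""
    two_m = W_sym.sum()
    k = W_sym.sum(axis=1)
    B = W_sym / two_m - np.outer(k, k) / two_m**2
    same = labels[:, None] == labels[None, :]
    return float(B[same].sum())


def exhaustive_best_modularity(W_sym: np.ndarray) -> tuple[float, np.ndarray]:
    """Globally optimal modularity by trying every set partition."""
    two_m = W_sym.sum()
    k = W_sym.sum(axis=1)
    B = W_sym / two_m - np.outer(k, k) / two_m**2
    best_q, best = -np.inf, None
    for labels in set_partitions(W_sym.shape[0]):
        same = labels[:, None] == labels[None, :]
        q = B[same].sum()
        if q > best_q:
            best_q, best = float(q), labels
    return best_q, best


def peel_coreness(adj: dict[str, set[str]]) -> dict[str, int]:
    """Coreness by literal peeling: for k = 0, 1, ... repeatedly delete
    nodes of degree < k; a node's coreness is the last k it survived."""
    core = {v: 0 for v in adj}
    k = 1
    alive = {v: set(ns) for v, ns in adj.items()}
    while alive:
        changed = True
        while changed:
            changed = False
            for v in list(alive):
                if len(alive[v]) < k:
                    for u in alive[v]:
                        alive[u].discard(v)
                    del alive[v]
                    changed = True
        for v in alive:
            core[v] = k
        k += 1
    return core


def random_digraph(rng: np.random.Generator, n_max: int = 8, p: float = 0.4):
    """Random weighted digraph as a dense matrix; at least one edge."""
    while True:
        n = int(rng.integers(3, n_max + 1))
        mask = rng.random((n, n)) < p
        np.fill_diagonal(mask, False)
        if mask.sum() == 0:
            continue
        W = np.where(mask, rng.uniform(0.1, 2.0, (n, n)), 0.0)
        return W
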