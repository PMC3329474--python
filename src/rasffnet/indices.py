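"""Transgressor and Detector Indices (TI / DI) on a network snapshot.

Two index families summarise each country's impact at a query date:

* **PageRank** — the TI is the weighted PageRank of the detector ->
  transgressor orientation (a country accumulates TI by being reported
  against, more so by active reporters), the DI is the weighted PageRank of
  the reversed orientation.  The two are computed independently.
* **HITS** — hubs and authorities on the detector -> transgressor
  orientation: the DI (hub score) is high for countries reporting against
  high-TI countries, and the TI (authority score) is high for countries
  reported by high-DI detectors; the two reinforce each other.

Every index vector is L1-normalized: scores are non-negative and sum to 1
across countries at any query date, so countries are directly comparable
and a score is a share of total activity.  For reporting, scores are
conventionally multiplied by 1000.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from datetime import date as Date

import numpy as np

from .decay import Snapshot, reverse


class Method(str, enum.Enum):
    PAGERANK = "pagerank"
    HITS = "hits"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class Role(str, enum.Enum):
    TI = "TI"
    DI = "DI"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class ConvergenceError(RuntimeError):
    """Iteration did not reach the tolerance within max_iter."""

    def __init__(self, what: str, residual: float, max_iter: int) -> None:
        super().__init__(
            f"{what} did not converge after {max_iter} iterations "
            f"(residual {residual:.3e})"
        )
        self.residual = residual


@dataclass(frozen=True)
class PageRankParams:
    """Damping factor, convergence tolerance and iteration cap."""

    damping: float = 0.85
    tol: float = 1e-10
    max_iter: int = 1000

    def __post_init__(self) -> None:
        if not 0 < self.damping < 1:
            raise ValueError("damping must lie in (0, 1)")
        if self.tol <= 0 or self.max_iter < 1:
            raise ValueError("tol must be > 0 and max_iter >= 1")


@dataclass(frozen=True)
class IndexVector:
    """Country -> score map for one method x role at one date; sums to 1."""

    method: Method
    role: Role
    query_date: Date
    scores: dict[str, float]
    report_scale: float = 1000.0
    label: str = ""  # e.g. the filter the snapshot was built under

    def __post_init__(self) -> None:
        total = sum(self.scores.values())
        if self.scores and abs(total - 1.0) > 1e-9:
            raise ValueError(f"scores must sum to 1, got {total!r}")
        if any(s < 0 for s in self.scores.values()):
            raise ValueError("scores must be non-negative")

    def __getitem__(self, country: str) -> float:
        return self.scores[country]

    def top(self, k: int = 10) -> list[tuple[str, float]]:
        """Highest-scoring countries; ties broken lexicographically."""
        return sorted(self.scores.items(), key=lambda kv: (-kv[1], kv[0]))[:k]


def scale_for_report(v: IndexVector) -> dict[str, float]:
    """Scores multiplied by ``report_scale`` (default 1000) for display;
    the vector itself is unchanged."""
    return {c: s * v.report_scale for c, s in v.scores.items()}


def _pagerank_scores(
    W: np.ndarray, damping: float, tol: float, max_iter: int
) -> np.ndarray:
    """Weighted PageRank by power iteration on a dense weight matrix.

    Rows with no out-weight (dangling nodes) teleport uniformly, which keeps
    the result a proper probability distribution.
    """
    n = W.shape[0]
    out = W.sum(axis=1)
    dangling = out == 0
    # Row-stochastic transition matrix; dangling rows handled separately.
    P = np.divide(W, np.where(dangling, 1.0, out)[:, None])
    x = np.full(n, 1.0 / n)
    for _ in range(max_iter):
        x_new = damping * (P.T @ x + x[dangling].sum() / n) + (1 - damping) / n
        residual = float(np.abs(x_new - x).sum())
        x = x_new
        if residual < tol:
            return x / x.sum()
    raise ConvergenceError("PageRank", residual, max_iter)


def pagerank_indices(
    snapshot: Snapshot, params: PageRankParams = PageRankParams()
) -> tuple[IndexVector, IndexVector]:
    """(TI, DI) by weighted PageRank; the two roles are independent.

    TI uses the snapshot's detector -> transgressor orientation, DI the
    reversed one.  A snapshot with no edges degenerates to the uniform
    teleportation distribution for both roles.
    """
    if snapshot.n_nodes == 0:
        raise ValueError("snapshot has no nodes")
    order = snapshot.sorted_nodes()

    def vector(snap: Snapshot, role: Role) -> IndexVector:
        scores = _pagerank_scores(
            snap.weight_matrix(), params.damping, params.tol, params.max_iter
        )
        return IndexVector(
            method=Method.PAGERANK,
            role=role,
            query_date=snapshot.query_date,
            scores=dict(zip(order, scores.tolist())),
            label=_filter_label(snapshot),
        )

    return vector(snapshot, Role.TI), vector(reverse(snapshot), Role.DI)


def _hits_scores(
    W: np.ndarray, tol: float, max_iter: int
) -> tuple[np.ndarray, np.ndarray]:
    """Weighted HITS mutual-reinforcement iteration.

    Internally L2-normalized for numerical stability; callers L1-normalize
    the converged fixed point.
    """
    n = W.shape[0]
    h = np.full(n, 1.0 / np.sqrt(n))
    a = np.zeros(n)
    for _ in range(max_iter):
        a_new = W.T @ h
        a_new /= np.linalg.norm(a_new)
        h_new = W @ a_new
        h_new /= np.linalg.norm(h_new)
        residual = float(np.abs(a_new - a).sum() + np.abs(h_new - h).sum())
        a, h = a_new, h_new
        if residual < tol:
            return h, a
    raise ConvergenceError("HITS", residual, max_iter)


def hits_indices(
    snapshot: Snapshot, tol: float = 1e-10, max_iter: int = 1000
) -> tuple[IndexVector, IndexVector]:
    """(TI, DI) by weighted HITS: TI = authority, DI = hub.

    Requires at least one edge — with no reports there is no
    mutual-reinforcement fixed point to speak of.
    """
    if snapshot.n_edges == 0:
        raise ValueError("HITS requires a snapshot with at least one edge")
    order = snapshot.sorted_nodes()
    h, a = _hits_scores(snapshot.weight_matrix(), tol, max_iter)

    def vector(x: np.ndarray, role: Role) -> IndexVector:
        x = np.clip(x, 0.0, None)
        x = x / x.sum()
        return IndexVector(
            method=Method.HITS,
            role=role,
            query_date=snapshot.query_date,
            scores=dict(zip(order, x.tolist())),
            label=_filter_label(snapshot),
        )

    return vector(a, Role.TI), vector(h, Role.DI)


def compute_indices(
    snapshot: Snapshot,
    method: Method | str = Method.PAGERANK,
    pagerank_params: PageRankParams = PageRankParams(),
    hits_tol: float = 1e-10,
    hits_max_iter: int = 1000,
) -> tuple[IndexVector, IndexVector]:
    """Dispatch to the requested index engine; returns (TI, DI)."""
    method = Method(method)
    if method is Method.PAGERANK:
        return pagerank_indices(snapshot, pagerank_params)
    return hits_indices(snapshot, hits_tol, hits_max_iter)


def _filter_label(snapshot: Snapshot) -> str:
    f = snapshot.filters_applied
    if not f:
        return "all"
    parts = [str(v) for v in f.values() if str(v) not in ("", "all")]
    return "+".join(parts) if parts else "all"
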