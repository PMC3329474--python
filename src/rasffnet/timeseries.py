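"""Index trajectories over date grids, tabular export and node colouring.

Trend lines answer the monitoring question — is a country's transgressor
share rising or falling — by recomputing the filtered snapshot and the
chosen index at every date of a grid.  Because every index vector is
normalized, a trajectory point is a share of that date's total activity and
trajectories of different countries are directly comparable.

Colour coding for network maps follows the red/green convention: red
intensity tracks transgressor activity, green detector activity, their mix
renders brownish, and opacity tracks the stronger of the two so marginal
actors fade out.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date as Date
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .decay import DecayParams, DEFAULT_DECAY, EmptySnapshotError, build_snapshot
from .indices import (
    IndexVector,
    Method,
    PageRankParams,
    Role,
    compute_indices,
    scale_for_report,
)
from .notifications import NotificationLog, filter_log


@dataclass(frozen=True)
class Trajectory:
    """Date-indexed series of index scores per country.

    ``series[c][i]`` is country ``c``'s score at ``dates[i]``; countries
    absent from a date's snapshot carry score 0 there, so each date's
    scores still sum to 1 across countries.
    """

    method: Method
    role: Role
    dates: tuple[Date, ...]
    series: dict[str, list[float]]

    def __post_init__(self) -> None:
        for country, vals in self.series.items():
            if len(vals) != len(self.dates):
                raise ValueError(
                    f"series for {country} has {len(vals)} values "
                    f"for {len(self.dates)} dates"
                )

    def to_frame(self, scale: float = 1.0) -> pd.DataFrame:
        """Long format: date, country, method, role, score, score_x1000."""
        rows = []
        for country in sorted(self.series):
            for d, s in zip(self.dates, self.series[country]):
                rows.append(
                    {
                        "date": d.isoformat(),
                        "country": country,
                        "method": self.method.value,
                        "role": self.role.value,
                        "score": s * scale,
                        "score_x1000": s * 1000.0,
                    }
                )
        return pd.DataFrame(
            rows, columns=["date", "country", "method", "role", "score", "score_x1000"]
        )

    def select(self, countries: Sequence[str]) -> "Trajectory":
        unknown = sorted(set(countries) - set(self.series))
        if unknown:
            raise KeyError(f"unknown country code(s): {', '.join(unknown)}")
        return Trajectory(
            self.method,
            self.role,
            self.dates,
            {c: self.series[c] for c in countries},
        )


def index_trajectory(
    log: NotificationLog,
    dates: Sequence[Date],
    method: Method | str = Method.PAGERANK,
    role: Role | str = Role.TI,
    category_filter="all",
    ntype_filter="all",
    decay: DecayParams = DEFAULT_DECAY,
    pagerank_params: PageRankParams = PageRankParams(),
) -> Trajectory:
    """Filter -> snapshot -> index at every grid date, assembled per country.

    The grid must be strictly increasing, and every date must yield a
    non-empty snapshot (the error names the offending date).
    """
    dates = tuple(dates)
    if any(b <= a for a, b in zip(dates, dates[1:])):
        raise ValueError("date grid must be strictly increasing")
    filtered = filter_log(log, category_filter, ntype_filter)
    filters = {"category": str(category_filter), "ntype": str(ntype_filter)}
    method = Method(method)
    role = Role(role)

    per_date: list[dict[str, float]] = []
    for d in dates:
        try:
            snap = build_snapshot(filtered, d, params=decay, filters_applied=filters)
        except EmptySnapshotError as exc:
            raise EmptySnapshotError(
                f"no notifications contribute at grid date {d.isoformat()}"
            ) from exc
        ti, di = compute_indices(snap, method, pagerank_params=pagerank_params)
        per_date.append((ti if role is Role.TI else di).scores)

    countries = sorted(set().union(*per_date))
    series = {
        c: [scores.get(c, 0.0) for scores in per_date] for c in countries
    }
    return Trajectory(method=method, role=role, dates=dates, series=series)


def monthly_grid(start: Date, end: Date) -> list[Date]:
    """First-of-month dates covering [start, end] — the default trend grid."""
    stamps = pd.date_range(start, end, freq="MS")
    grid = [ts.date() for ts in stamps]
    if not grid or grid[0] > start:
        grid.insert(0, start)
    return grid


def read_trajectory(path: str | Path) -> Trajectory:
    """Re-load a trajectory written by ``to_frame().to_csv`` (long format)."""
    df = pd.read_csv(path, dtype={"country": str})
    dates = tuple(
        sorted({Date.fromisoformat(d) for d in df["date"].astype(str)})
    )
    method = Method(df["method"].iloc[0])
    role = Role(df["role"].iloc[0])
    series: dict[str, list[float]] = {}
    index = {d: i for i, d in enumerate(dates)}
    for country, sub in df.groupby("country"):
        vals = [0.0] * len(dates)
        for d, s in zip(sub["date"], sub["score"]):
            vals[index[Date.fromisoformat(str(d))]] = float(s)
        series[str(country)] = vals
    return Trajectory(method=method, role=role, dates=dates, series=series)


@dataclass(frozen=True)
class NodeColor:
    """Red/green/alpha render colour; components clamped to [0, 1]."""

    red: float
    green: float
    alpha: float

    def __post_init__(self) -> None:
        for name in ("red", "green", "alpha"):
            v = getattr(self, name)
            object.__setattr__(self, name, min(1.0, max(0.0, v)))

    def to_rgba(self) -> tuple[float, float, float, float]:
        return (self.red, self.green, 0.0, self.alpha)

    def to_hex(self) -> str:
        r, g, b, a = self.to_rgba()
        return "#{:02x}{:02x}{:02x}{:02x}".format(
            round(r * 255), round(g * 255), round(b * 255), round(a * 255)
        )


def default_strength_scale(ti: IndexVector, di: IndexVector) -> float:
    """1 / (95th percentile of the pooled index values), so colour
    saturates for the top actors at the query date."""
    vals = np.array(list(ti.scores.values()) + list(di.scores.values()))
    p95 = float(np.percentile(vals, 95))
    return 1.0 / p95 if p95 > 0 else 1.0


def node_colors(
    ti: IndexVector,
    di: IndexVector,
    strength_scale: float | None = None,
) -> dict[str, NodeColor]:
    """Map each country to its render colour.

    Red intensity is the (scaled, clamped) TI, green the DI, and opacity the
    larger of the two: strong transgressors render deep red, strong
    detectors deep green, dual-role countries brownish, and countries with
    negligible activity in both roles come out transparent.
    """
    if set(ti.scores) != set(di.scores):
        raise ValueError("TI and DI vectors cover different country sets")
    if strength_scale is None:
        strength_scale = default_strength_scale(ti, di)
    if strength_scale <= 0:
        raise ValueError("strength_scale must be positive")
    colors = {}
    for c in ti.scores:
        red = min(1.0, ti.scores[c] * strength_scale)
        green = min(1.0, di.scores[c] * strength_scale)
        colors[c] = NodeColor(red=red, green=green, alpha=max(red, green))
    return colors


def vectors_to_frame(vectors: Sequence[IndexVector]) -> pd.DataFrame:
    """Long-format table for a list of index vectors."""
    rows = []
    for v in vectors:
        scaled = scale_for_report(v)
        for country in sorted(v.scores):
            rows.append(
                {
                    "country": country,
                    "method": v.method.value,
                    "role": v.role.value,
                    "date": v.query_date.isoformat(),
                    "filter": v.label,
                    "score": v.scores[country],
                    "score_x1000": scaled[country],
                }
            )
    return pd.DataFrame(
        rows,
        columns=["country", "method", "role", "date", "filter", "score", "score_x1000"],
    )


def pivot_table(vectors: Sequence[IndexVector]) -> pd.DataFrame:
    """Report-shaped pivot: one (country, role) row per country block, one
    column per filter label, values scaled by ``report_scale``."""
    long = vectors_to_frame(vectors)
    return long.pivot_table(
        index=["country", "role"],
        columns="filter",
        values="score_x1000",
        aggfunc="first",
        sort=True,
    )


def export_table(
    vectors: Sequence[IndexVector],
    path: str | Path,
    mode: str = "long",
) -> Path:
    """Write index vectors to CSV (``.xlsx`` paths get a spreadsheet).

    ``mode='long'`` emits one row per (country, method, role, date);
    ``mode='pivot'`` emits the country-block x filter-column report shape.
    """
    path = Path(path)
    if mode == "long":
        table = vectors_to_frame(vectors)
        index = False
    elif mode == "pivot":
        table = pivot_table(vectors)
        index = True
    else:
        raise ValueError(f"unknown export mode {mode!r}")
    if path.suffix.lower() == ".xlsx":
        table.to_excel(path, index=index)
    else:
        table.to_csv(path, index=index)
    return path


def write_colored_graphml(
    snapshot_graph, colors: dict[str, NodeColor], path: str | Path
) -> Path:
    """Stamp node colours into a networkx graph and write GraphML."""
    import networkx as nx

    g = snapshot_graph.copy()
    for node, col in colors.items():
        if node in g:
            g.nodes[node]["red"] = col.red
            g.nodes[node]["green"] = col.green
            g.nodes[node]["alpha"] = col.alpha
            g.nodes[node]["color_hex"] = col.to_hex()
    nx.write_graphml(g, Path(path))
    return Path(path)


def plot_trajectory(
    traj: Trajectory,
    countries: Sequence[str] | None = None,
    scale: float = 1000.0,
    path: str | Path | None = None,
):
    """Trend-line plot of scaled index scores; saves to ``path`` if given."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    traj_sel = traj.select(countries) if countries else traj
    fig, ax = plt.subplots(figsize=(8, 4.5))
    for country in sorted(traj_sel.series):
        ax.plot(
            [d.isoformat() for d in traj_sel.dates],
            [s * scale for s in traj_sel.series[country]],
            marker="o",
            markersize=2.5,
            label=country,
        )
    ax.set_xlabel("date")
    ax.set_ylabel(f"{traj.role.value} x {scale:g} ({traj.method.value})")
    ax.legend(fontsize=8, ncols=2)
    ax.tick_params(axis="x", labelrotation=75, labelsize=7)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
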