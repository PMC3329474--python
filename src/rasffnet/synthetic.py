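"""Synthetic notification-log generator with planted statistical structure.

Real surveillance extracts are not redistributable, so every pipeline stage
is exercised on generated logs that emulate the stream's coarse statistics:
a pool of detector countries (EU member states in the real system) reporting
against a wider pool of transgressors, dates uniform over the study window,
notification types with a border-rejection share, and hazard texts drawn as
contaminant keywords so the keyword categorizer reproduces a target category
mixture.  Scenario knobs plant recoverable structure: per-country detect and
transgress rates (a 3x-rate country should surface as the top transgressor
index) and dated rate-change events (a rate zeroed at an intervention date
should produce a decaying transgressor trajectory, the remediation pattern).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date as Date, timedelta
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .notifications import (
    Category,
    DEFAULT_TABLE,
    KeywordTable,
    Notification,
    NotificationLog,
    NType,
)

#: Category mixture of the categorized stream (shares of categorized
#: notifications): mycotoxins dominate, then bacteria, chemicals, metals.
DEFAULT_CATEGORY_MIX: dict[Category, float] = {
    Category.MYCOTOXIN: 0.5045,
    Category.BACTERIA: 0.2026,
    Category.METAL: 0.1095,
    Category.CHEMICAL: 0.1554,
    Category.OTHER: 0.0280,
}


@dataclass(frozen=True)
class CountryProfile:
    """Per-country activity rates (arbitrary positive units; draws are
    proportional)."""

    code: str
    detect_rate: float = 0.0
    transgress_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.detect_rate < 0 or self.transgress_rate < 0:
            raise ValueError(f"{self.code}: rates must be non-negative")


@dataclass(frozen=True)
class RateChange:
    """From ``date`` on, ``country``'s transgress rate becomes ``new_rate``."""

    country: str
    date: Date
    new_rate: float


@dataclass
class ScenarioConfig:
    """Full specification of a synthetic notification stream."""

    countries: Sequence[CountryProfile]
    start: Date
    end: Date
    n_notifications: int
    category_mix: dict[Category, float] = field(
        default_factory=lambda: dict(DEFAULT_CATEGORY_MIX)
    )
    border_rejection_prob: float = 0.25
    rate_change_events: Sequence[RateChange] = ()
    allow_self_pairs: bool = False
    detector_pool: Sequence[str] | None = None  # None: every detect_rate > 0
    seed: int = 0

    def __post_init__(self) -> None:
        self.category_mix = {Category(k): float(v) for k, v in self.category_mix.items()}
        total = sum(self.category_mix.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"category_mix must sum to 1, got {total}")
        if not 0 <= self.border_rejection_prob <= 1:
            raise ValueError("border_rejection_prob must lie in [0, 1]")
        if self.n_notifications < 1:
            raise ValueError("n_notifications must be positive")
        if self.end < self.start:
            raise ValueError("end date precedes start date")


def _transgress_rates(
    config: ScenarioConfig, at: Date
) -> dict[str, float]:
    rates = {c.code: c.transgress_rate for c in config.countries}
    for ev in config.rate_change_events:
        if ev.date <= at:
            rates[ev.country] = ev.new_rate
    return rates


def generate_log(config: ScenarioConfig, table: KeywordTable = DEFAULT_TABLE) -> NotificationLog:
    """Draw a date-sorted log of ``n_notifications`` records.

    Per record: date uniform over the window; detector drawn from the
    detector pool proportionally to detect_rate; transgressor drawn
    proportionally to the transgress rate in force at that date (self-pairs
    resampled unless allowed); category from ``category_mix``, with the
    hazard text a keyword sampled from that category's table row.
    Deterministic under a fixed seed.
    """
    rng = np.random.default_rng(config.seed)
    codes = [c.code for c in config.countries]
    pool = list(config.detector_pool) if config.detector_pool is not None else [
        c.code for c in config.countries if c.detect_rate > 0
    ]
    det_rates = np.array(
        [next(c.detect_rate for c in config.countries if c.code == p) for p in pool]
    )
    if len(pool) == 0 or det_rates.sum() <= 0:
        raise ValueError("infeasible scenario: no detector with positive rate")
    if all(c.transgress_rate <= 0 for c in config.countries) and not any(
        ev.new_rate > 0 for ev in config.rate_change_events
    ):
        raise ValueError("infeasible scenario: no transgressor with positive rate")
    det_p = det_rates / det_rates.sum()

    n_days = (config.end - config.start).days
    cats = list(config.category_mix)
    cat_p = np.array([config.category_mix[c] for c in cats])

    records = []
    offsets = np.sort(rng.integers(0, n_days + 1, size=config.n_notifications))
    for off in offsets:
        day = config.start + timedelta(days=int(off))
        detector = pool[rng.choice(len(pool), p=det_p)]
        t_rates = _transgress_rates(config, day)
        t_codes = codes
        t_p = np.array([t_rates[c] for c in t_codes], dtype=float)
        if not config.allow_self_pairs:
            t_p = t_p.copy()
            t_p[t_codes.index(detector)] = 0.0
        if t_p.sum() <= 0:
            raise ValueError(
                f"infeasible scenario: no eligible transgressor on {day.isoformat()}"
            )
        transgressor = t_codes[rng.choice(len(t_codes), p=t_p / t_p.sum())]
        category = cats[rng.choice(len(cats), p=cat_p)]
        words = table.keywords[category]
        hazard = words[rng.integers(len(words))]
        if config.border_rejection_prob and rng.random() < config.border_rejection_prob:
            ntype = NType.BORDER_REJECTION
        else:
            ntype = NType.ALERT if rng.random() < 0.5 else NType.INFORMATION
        records.append(
            Notification(
                date=day,
                detector=detector,
                transgressor=transgressor,
                ntype=ntype,
                hazard_text=hazard,
            ).with_category(table)
        )
    return NotificationLog(records, provenance=f"synthetic(seed={config.seed})")


def default_scenario(
    seed: int = 0, n_notifications: int = 2000
) -> ScenarioConfig:
    """A plausible study-window scenario: a handful of high-volume EU
    detectors that also transgress, plus non-EU countries that only appear
    as transgressors."""
    countries = [
        CountryProfile("DEU", detect_rate=5.0, transgress_rate=1.5),
        CountryProfile("ITA", detect_rate=4.0, transgress_rate=1.0),
        CountryProfile("ESP", detect_rate=3.0, transgress_rate=1.5),
        CountryProfile("GBR", detect_rate=2.5, transgress_rate=0.5),
        CountryProfile("NLD", detect_rate=2.0, transgress_rate=0.8),
        CountryProfile("FRA", detect_rate=2.0, transgress_rate=1.0),
        CountryProfile("DNK", detect_rate=1.0, transgress_rate=0.2),
        CountryProfile("POL", detect_rate=1.0, transgress_rate=0.5),
        CountryProfile("IRN", transgress_rate=5.0),
        CountryProfile("CHN", transgress_rate=3.0),
        CountryProfile("TUR", transgress_rate=2.5),
        CountryProfile("IND", transgress_rate=2.0),
        CountryProfile("BRA", transgress_rate=1.5),
        CountryProfile("ARG", transgress_rate=1.0),
        CountryProfile("USA", transgress_rate=1.0),
        CountryProfile("THA", transgress_rate=0.8),
    ]
    return ScenarioConfig(
        countries=countries,
        start=Date(2003, 5, 1),
        end=Date(2008, 8, 31),
        n_notifications=n_notifications,
        seed=seed,
    )


def load_scenario(path: str | Path) -> ScenarioConfig:
    """Read a scenario from a YAML file.

    Schema: ``countries`` (list of {code, detect_rate, transgress_rate}),
    ``start``, ``end`` (ISO dates), ``n_notifications``, and optionally
    ``category_mix``, ``border_rejection_prob``, ``rate_change_events``
    (list of {country, date, new_rate}), ``allow_self_pairs``,
    ``detector_pool``, ``seed``.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    countries = [
        CountryProfile(
            code=c["code"],
            detect_rate=float(c.get("detect_rate", 0.0)),
            transgress_rate=float(c.get("transgress_rate", 0.0)),
        )
        for c in raw["countries"]
    ]
    events = [
        RateChange(
            country=e["country"],
            date=_as_date(e["date"]),
            new_rate=float(e["new_rate"]),
        )
        for e in raw.get("rate_change_events", [])
    ]
    kwargs = {}
    if "category_mix" in raw:
        kwargs["category_mix"] = {
            Category(k): float(v) for k, v in raw["category_mix"].items()
        }
    for key in ("border_rejection_prob", "allow_self_pairs", "detector_pool", "seed"):
        if key in raw:
            kwargs[key] = raw[key]
    return ScenarioConfig(
        countries=countries,
        start=_as_date(raw["start"]),
        end=_as_date(raw["end"]),
        n_notifications=int(raw["n_notifications"]),
        rate_change_events=events,
        **kwargs,
    )


def _as_date(value) -> Date:
    return value if isinstance(value, Date) else Date.fromisoformat(str(value))
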