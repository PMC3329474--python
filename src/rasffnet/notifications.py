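"""Notification records: data model, delimited-text I/O, hazard
categorization and filtering.

A *notification* is one logged report in a food-safety surveillance system:
a detector country flags a faulty product originating from a transgressor
country, on a date, with a notification type and a free-text hazard
description.  Hazards are assigned to contaminant categories by
case-insensitive keyword matching against a fixed keyword table (heavy
metals, mycotoxins, bacteria, chemicals, other); text matching no keyword is
*uncategorized* and still participates in the unfiltered network.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field, replace
from datetime import date as Date
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd

from .countries import validate_codes


class Category(str, enum.Enum):
    """Contaminant category of a notification."""

    METAL = "metal"
    MYCOTOXIN = "mycotoxin"
    BACTERIA = "bacteria"
    CHEMICAL = "chemical"
    OTHER = "other"
    UNCATEGORIZED = "uncategorized"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class NType(str, enum.Enum):
    """Notification type as labelled in the source system."""

    ALERT = "alert"
    INFORMATION = "information"
    BORDER_REJECTION = "border_rejection"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Contaminant categories in keyword-table row order; the order is the
#: tie-break when a hazard text matches keywords from several categories.
CATEGORY_ORDER: tuple[Category, ...] = (
    Category.METAL,
    Category.MYCOTOXIN,
    Category.BACTERIA,
    Category.CHEMICAL,
    Category.OTHER,
)

#: Default keyword table: contaminant components with high occurrence in the
#: surveillance stream, used to auto-assign a category to each notification.
DEFAULT_KEYWORDS: dict[Category, tuple[str, ...]] = {
    Category.METAL: ("arsenic", "lead", "mercury", "cadmium"),
    Category.MYCOTOXIN: ("aflatoxin", "fumonisin", "ochratoxin"),
    Category.BACTERIA: ("salmonella", "bacillus cereus", "listeria monocytogenes"),
    Category.CHEMICAL: (
        "benzoic acid",
        "colour sudan 1",
        "methomyl",
        "nitrofuran",
        "sulphites",
    ),
    Category.OTHER: ("chloramphenicol", "dioxins", "methamidophos"),
}


@dataclass(frozen=True)
class KeywordTable:
    """Mapping category -> keywords used for hazard categorization.

    Keywords are stored lower-cased and must be non-empty and unique within
    a category.  ``CATEGORY_ORDER`` fixes the precedence between categories
    when several match the same text.
    """

    keywords: dict[Category, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_KEYWORDS)
    )

    def __post_init__(self) -> None:
        normalized: dict[Category, tuple[str, ...]] = {}
        for cat, words in self.keywords.items():
            cat = Category(cat)
            low = tuple(w.lower().strip() for w in words)
            if not low or any(not w for w in low):
                raise ValueError(f"category {cat.value!r} has an empty keyword")
            if len(set(low)) != len(low):
                raise ValueError(f"duplicate keyword within category {cat.value!r}")
            normalized[cat] = low
        object.__setattr__(self, "keywords", normalized)

    def categories(self) -> tuple[Category, ...]:
        return tuple(c for c in CATEGORY_ORDER if c in self.keywords)


DEFAULT_TABLE = KeywordTable()


def match_categories(text: str, table: KeywordTable = DEFAULT_TABLE) -> list[Category]:
    """All categories whose keywords occur in ``text`` (case-insensitive
    substring match), in table row order.  Diagnostics companion of
    :func:`categorize_hazard`."""
    low = text.lower()
    return [
        cat
        for cat in table.categories()
        if any(word in low for word in table.keywords[cat])
    ]


def categorize_hazard(text: str, table: KeywordTable = DEFAULT_TABLE) -> Category:
    """Assign a contaminant category to a hazard description.

    Matching is case-insensitive substring matching of the table's keywords
    against the raw text (no stemming).  Text matching no keyword maps to
    :attr:`Category.UNCATEGORIZED`.  When keywords from several categories
    match, the first category in table row order wins and a warning is
    emitted; use :func:`match_categories` to inspect all matches.
    """
    matches = match_categories(text, table)
    if not matches:
        return Category.UNCATEGORIZED
    if len(matches) > 1:
        warnings.warn(
            f"hazard text matches multiple categories "
            f"{[c.value for c in matches]}; keeping {matches[0].value!r}",
            stacklevel=2,
        )
    return matches[0]


@dataclass(frozen=True)
class Notification:
    """One logged report: detector flags a product from transgressor."""

    date: Date
    detector: str
    transgressor: str
    ntype: NType
    hazard_text: str
    category: Category = Category.UNCATEGORIZED
    matched_categories: tuple[Category, ...] = ()

    @property
    def is_self_report(self) -> bool:
        """Detector and transgressor are the same country (permitted)."""
        return self.detector == self.transgressor

    def with_category(self, table: KeywordTable = DEFAULT_TABLE) -> "Notification":
        matches = match_categories(self.hazard_text, table)
        cat = matches[0] if matches else Category.UNCATEGORIZED
        return replace(self, category=cat, matched_categories=tuple(matches))


class NotificationLog:
    """Ordered, filterable collection of notifications."""

    def __init__(
        self, records: Iterable[Notification], provenance: str = ""
    ) -> None:
        self.records: list[Notification] = list(records)
        self.provenance = provenance

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[Notification]:
        return iter(self.records)

    def __getitem__(self, i):
        return self.records[i]

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, NotificationLog) and self.records == other.records
        )

    def sorted_by_date(self) -> "NotificationLog":
        return NotificationLog(
            sorted(self.records, key=lambda r: r.date), self.provenance
        )

    def date_range(self) -> tuple[Date, Date]:
        if not self.records:
            raise ValueError("empty log has no date range")
        dates = [r.date for r in self.records]
        return min(dates), max(dates)

    def countries(self) -> set[str]:
        out: set[str] = set()
        for r in self.records:
            out.add(r.detector)
            out.add(r.transgressor)
        return out

    def to_frame(self) -> pd.DataFrame:
        """Tabular view with the writer's column schema."""
        return pd.DataFrame(
            {
                "date": [r.date.isoformat() for r in self.records],
                "detector": [r.detector for r in self.records],
                "transgressor": [r.transgressor for r in self.records],
                "type": [r.ntype.value for r in self.records],
                "hazard": [r.hazard_text for r in self.records],
                "category": [r.category.value for r in self.records],
            }
        )


REQUIRED_COLUMNS = ("date", "detector", "transgressor", "type", "hazard")


def _parse_date(value: str, row: int) -> Date:
    try:
        return Date.fromisoformat(str(value).strip())
    except ValueError as exc:
        raise ValueError(f"row {row}: unparsable ISO date {value!r}") from exc


def read_log(
    path: str | Path,
    delimiter: str = ",",
    table: KeywordTable = DEFAULT_TABLE,
    allow_unknown_countries: bool = False,
) -> NotificationLog:
    """Read a notification log from delimited text (CSV by default).

    The file must have a header with columns ``date, detector,
    transgressor, type, hazard`` (extra columns, e.g. a previously written
    ``category``, are ignored; the category is always re-derived from the
    hazard text).  Dates are ISO-8601.  Rows whose ``type`` is not one of
    ``alert, information, border_rejection`` are reported together in one
    error.  Country codes are checked against the ISO alpha-3 list unless
    ``allow_unknown_countries``.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"{path}: empty file") from exc
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s): {', '.join(missing)}")
    if df.empty:
        raise ValueError(f"{path}: no data rows")

    bad_types = [
        (i + 2, t)  # +2: header line + 1-based numbering
        for i, t in enumerate(df["type"])
        if t.strip() not in NType._value2member_map_
    ]
    if bad_types:
        listing = "; ".join(f"line {ln}: {t!r}" for ln, t in bad_types[:20])
        raise ValueError(f"{path}: unknown notification type(s): {listing}")

    records = []
    for i, row in enumerate(df.itertuples(index=False)):
        note = Notification(
            date=_parse_date(row.date, i + 2),
            detector=row.detector.strip(),
            transgressor=row.transgressor.strip(),
            ntype=NType(row.type.strip()),
            hazard_text=row.hazard,
        ).with_category(table)
        records.append(note)
    validate_codes(
        [r.detector for r in records] + [r.transgressor for r in records],
        allow_unknown=allow_unknown_countries,
    )
    return NotificationLog(records, provenance=str(path))


def write_log(log: NotificationLog, path: str | Path, delimiter: str = ",") -> Path:
    """Write a log as delimited text with a derived ``category`` column."""
    path = Path(path)
    log.to_frame().to_csv(path, sep=delimiter, index=False)
    return path


#: Filter tokens accepted beyond plain categories.  ``all`` keeps every
#: record including uncategorized ones; ``microorganism`` is the union of
#: the two microbiological categories (mycotoxins + bacteria).
MICROORGANISM = "microorganism"
ALL = "all"


def _resolve_category_filter(category_filter) -> set[Category] | None:
    if category_filter is None:
        return None
    if isinstance(category_filter, (set, frozenset, list, tuple)) and not isinstance(
        category_filter, str
    ):
        out: set[Category] = set()
        for item in category_filter:
            sub = _resolve_category_filter(item)
            if sub is None:
                return None
            out |= sub
        return out
    token = (
        category_filter.value
        if isinstance(category_filter, Category)
        else str(category_filter).lower()
    )
    if token == ALL:
        return None
    if token == MICROORGANISM:
        return {Category.MYCOTOXIN, Category.BACTERIA}
    try:
        return {Category(token)}
    except ValueError as exc:
        raise ValueError(f"unknown category filter token {token!r}") from exc


def filter_log(
    log: NotificationLog,
    category_filter="all",
    ntype_filter="all",
) -> NotificationLog:
    """Restrict a log by contaminant category and/or notification type.

    ``category_filter`` is ``"all"``, a category name, ``"microorganism"``
    (mycotoxin + bacteria) or a set of these; ``"all"`` keeps uncategorized
    records.  ``ntype_filter`` is ``"all"`` or ``"border_rejection"``.
    An empty result is a valid (empty) log, not an error.
    """
    cats = _resolve_category_filter(category_filter)

    ntoken = (
        ntype_filter.value
        if isinstance(ntype_filter, NType)
        else str(ntype_filter).lower()
    )
    if ntoken == ALL:
        ntype = None
    elif ntoken in NType._value2member_map_:
        ntype = NType(ntoken)
    else:
        raise ValueError(f"unknown notification-type filter token {ntoken!r}")

    kept = [
        r
        for r in log
        if (cats is None or r.category in cats)
        and (ntype is None or r.ntype == ntype)
    ]
    return NotificationLog(kept, provenance=log.provenance)
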