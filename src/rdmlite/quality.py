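"""Data-quality profiling: rule conformance, completeness, summary aggregates.

Every live cell is classified into exactly one of three states:

* **missing** — null after cleaning, or violating a rule whose severity is
  ``missing``;
* **wrong** — violating a rule whose severity is ``wrong`` (or
  ``invalidates_row``, which should not normally reach live), or failing
  the column's semantic type (unparseable integer/decimal/date);
* **correct** — everything else.

So ``correct + missing + wrong == row count`` for every column and every
period.  Accuracy maps to rule conformance, completeness to the null rate,
consistency to lookup membership, timeliness to load recency, and
uniqueness to duplicate primary keys (zero by construction of the live
table).  Accessibility and access security are organisational properties
and appear only as report metadata flags.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime

from .catalogue import CatalogueEntry, CatalogueItem, LookupRef, parse_iso_date
from .errors import QualityError
from .store import Store

CLASSES = ("correct", "missing", "wrong")


def classify_value(item: CatalogueItem, value: str | None, lookups: dict[str, LookupRef]) -> str:
    if value is None:
        return "missing"
    for rule in item.validation_rules:
        if rule.rule_kind == "not_null":
            continue  # value is present
        if rule.violated_by(value, lookups):
            return "missing" if rule.severity == "missing" else "wrong"
    if item.semantic_type == "integer":
        try:
            int(value)
        except ValueError:
            return "wrong"
    elif item.semantic_type == "decimal":
        try:
            float(value)
        except ValueError:
            return "wrong"
    elif item.semantic_type == "date":
        if parse_iso_date(value) is None:
            return "wrong"
    return "correct"


def event_month(entry: CatalogueEntry, row: dict) -> str:
    """Calendar month bucket (YYYY-MM) of a row; 'undated' if null/invalid."""
    col = entry.event_date_column
    if col is None:
        return "undated"
    value = row.get(col)
    if value is None or parse_iso_date(value) is None:
        return "undated"
    return value[:7]


def _empty_counts(columns: list[str]) -> dict:
    return {c: {"correct": 0, "missing": 0, "wrong": 0} for c in columns}


@dataclass
class QualityReport:
    """Per-column and per-period conformance counts for one dataset."""

    dataset_id: str
    dataset_name: str
    generated_at: str
    row_count: int
    per_column: dict
    per_period: dict  # month -> {column -> counts}; empty if no event date column
    duplicate_primary_keys: int
    days_since_last_load: float | None
    dimension_flags: dict = field(
        default_factory=lambda: {
            "accessibility": "organisational; not computed from data",
            "access_security": "organisational; not computed from data",
            "relevancy": "out of computed scope",
        }
    )

    def column_totals(self) -> dict:
        totals = {k: 0 for k in CLASSES}
        for counts in self.per_column.values():
            for k in CLASSES:
                totals[k] += counts[k]
        return totals

    def to_dict(self) -> dict:
        return {
            "dataset_id": self.dataset_id,
            "dataset_name": self.dataset_name,
            "generated_at": self.generated_at,
            "row_count": self.row_count,
            "per_column": self.per_column,
            "per_period": self.per_period,
            "duplicate_primary_keys": self.duplicate_primary_keys,
            "days_since_last_load": self.days_since_last_load,
            "dimension_flags": dict(self.dimension_flags),
        }


def classify_rows(entry: CatalogueEntry, rows: list[dict], columns: list[str] | None = None):
    """Classify rows and return (per_column, per_period) count dicts."""
    lookups = entry.lookup_map()
    columns = columns if columns is not None else entry.column_names()
    per_column = _empty_counts(columns)
    per_period: dict[str, dict] = {}
    bucketed = entry.event_date_column is not None
    for row in rows:
        month = event_month(entry, row) if bucketed else None
        if bucketed and month not in per_period:
            per_period[month] = _empty_counts(columns)
        for col in columns:
            cls = classify_value(entry.item(col), row.get(col), lookups)
            per_column[col][cls] += 1
            if bucketed:
                per_period[month][col][cls] += 1
    return per_column, per_period


def evaluate_quality(store: Store, dataset_ref: str, *, now: datetime | None = None) -> QualityReport:
    """Profile the live table of a dataset against its catalogue rules."""
    entry = store.catalogue.resolve(dataset_ref)
    live, _ = store.dataset_state(entry.dataset_id)
    rows = [rec.values for rec in live.values()]
    per_column, per_period = classify_rows(entry, rows)

    # live is keyed on the primary key, so duplicates are zero by construction;
    # recount anyway so the report states a measured value
    keys = [tuple(r.get(c) for c in entry.primary_key) for r in rows] if entry.primary_key else []
    duplicates = len(keys) - len(set(keys))

    last = store.last_load_time.get(entry.dataset_id)
    days = None
    if last is not None:
        now = now or datetime.now()
        days = (now - last).total_seconds() / 86400.0
    return QualityReport(
        dataset_id=entry.dataset_id,
        dataset_name=entry.name,
        generated_at=(now or datetime.now()).isoformat(),
        row_count=len(rows),
        per_column=per_column,
        per_period=per_period,
        duplicate_primary_keys=duplicates,
        days_since_last_load=days,
    )


@dataclass
class SummaryAggregate:
    """Record counts grouped by a column's values or by event month."""

    dataset_id: str
    dimension: str
    cells: dict  # value -> count; nulls under "(null)"
    total: int

    def to_dict(self) -> dict:
        return {
            "dataset_id": self.dataset_id,
            "dimension": self.dimension,
            "cells": dict(self.cells),
            "total": self.total,
        }


def build_summary_aggregate(
    store: Store, dataset_ref: str, dimension: str, *, max_cardinality: int = 1000
) -> SummaryAggregate:
    """Group live records by a column's value or by calendar month."""
    entry = store.catalogue.resolve(dataset_ref)
    live, _ = store.dataset_state(entry.dataset_id)
    rows = [rec.values for rec in live.values()]
    if dimension == "month":
        if entry.event_date_column is None:
            raise QualityError(f"dataset {entry.name!r} has no event date column for month aggregation")
        values = [event_month(entry, r) for r in rows]
    else:
        if not entry.has_column(dimension):
            raise QualityError(f"dataset {entry.name!r} has no column {dimension!r}")
        values = [r.get(dimension) if r.get(dimension) is not None else "(null)" for r in rows]
    cells: dict[str, int] = {}
    for v in values:
        cells[v] = cells.get(v, 0) + 1
        if len(cells) > max_cardinality:
            raise QualityError(
                f"dimension {dimension!r} exceeds {max_cardinality} distinct values; "
                "aggregate a coded or date column instead"
            )
    return SummaryAggregate(
        dataset_id=entry.dataset_id,
        dimension=dimension,
        cells=dict(sorted(cells.items())),
        total=len(rows),
    )


def _month_range(months: list[str]) -> list[str]:
    """Contiguous YYYY-MM sequence spanning the observed months."""
    if not months:
        return []
    y0, m0 = map(int, min(months).split("-"))
    y1, m1 = map(int, max(months).split("-"))
    out = []
    y, m = y0, m0
    while (y, m) <= (y1, m1):
        out.append(f"{y:04d}-{m:02d}")
        m += 1
        if m == 13:
            y, m = y + 1, 1
    return out


def render_quality_timeline(store: Store, dataset_ref: str, *, chart_path: str | None = None) -> dict:
    """Per-month correct/missing/wrong series over a contiguous month axis.

    Months with no records appear as explicit zero points, so accrual gaps
    are visible.  Totals equal :func:`evaluate_quality` totals.
    """
    entry = store.catalogue.resolve(dataset_ref)
    if entry.event_date_column is None:
        raise QualityError(f"dataset {entry.name!r} has no event date column")
    report = evaluate_quality(store, entry.dataset_id)
    dated = [m for m in report.per_period if m != "undated"]
    months = _month_range(dated)
    series = {cls: [] for cls in CLASSES}
    records = []
    for month in months:
        counts = report.per_period.get(month, _empty_counts(entry.column_names()))
        n_rows = 0
        for cls in CLASSES:
            total = sum(counts[c][cls] for c in counts)
            series[cls].append(total)
        if counts:
            any_col = next(iter(counts))
            n_rows = sum(counts[any_col][cls] for cls in CLASSES)
        records.append(n_rows)
    undated = report.per_period.get("undated")
    undated_records = 0
    if undated:
        any_col = next(iter(undated))
        undated_records = sum(undated[any_col][cls] for cls in CLASSES)
    timeline = {
        "dataset_id": entry.dataset_id,
        "months": months,
        "correct": series["correct"],
        "missing": series["missing"],
        "wrong": series["wrong"],
        "records": records,
        "undated_records": undated_records,
    }
    if chart_path is not None:
        _plot_timeline(entry.name, timeline, chart_path)
    return timeline


def _plot_timeline(name: str, timeline: dict, path: str) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 3.5))
    x = range(len(timeline["months"]))
    ax.bar(x, timeline["correct"], label="correct", color="#4c9f70")
    bottom = list(timeline["correct"])
    ax.bar(x, timeline["missing"], bottom=bottom, label="missing", color="#e0a84c")
    bottom = [a + b for a, b in zip(bottom, timeline["missing"])]
    ax.bar(x, timeline["wrong"], bottom=bottom, label="wrong", color="#c94f4f")
    ax.set_xticks(list(x))
    ax.set_xticklabels(timeline["months"], rotation=45, ha="right", fontsize=7)
    ax.set_ylabel("cell count")
    ax.set_title(f"{name}: monthly quality")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
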