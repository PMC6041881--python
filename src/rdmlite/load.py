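"""The load engine: RAW → STAGING → LIVE with audit logging and row history.

Each feed file passes through three stages.  RAW parses the file (resolving
renamed or absent headers via the catalogue's load logic) and records the
MD5 digest of the raw bytes.  STAGING applies the cleaning steps in order
and rejects rows that violate an ``invalidates_row`` rule, lack a primary
key, or duplicate an earlier in-batch key.  LIVE upserts staged rows keyed
on the catalogue-declared primary key; a superseded row moves to the
archive with ``valid_to`` set to the load time, which makes the repository
reconstructible exactly as it stood at any past instant.

Conservation invariants, checked by :meth:`LoadJob.check_conservation`:
``staged + rejected == raw`` and ``inserted + updated + unchanged == staged``.
"""

from __future__ import annotations

import csv
import hashlib
import io
from dataclasses import dataclass, field
from datetime import datetime, timedelta

import pandas as pd

from .catalogue import CatalogueEntry
from .errors import LoadError
from .store import ArchiveRecord, LiveRecord, Store

STAGES = ("RAW", "STAGING", "LIVE", "FAILED")
LEVELS = ("info", "warning", "fatal")


@dataclass
class LoadLogEntry:
    level: str
    message: str
    row_ref: int | None = None

    def to_dict(self) -> dict:
        return {"level": self.level, "message": self.message, "row_ref": self.row_ref}

    @classmethod
    def from_dict(cls, d: dict) -> "LoadLogEntry":
        return cls(**d)


@dataclass
class LoadJob:
    """One staged load of one feed file, with counts and a structured log."""

    job_id: str
    dataset_id: str
    source_path: str
    file_digest: str
    started_at: datetime
    finished_at: datetime | None = None
    stage: str = "RAW"
    raw_row_count: int = 0
    staged_row_count: int = 0
    rejected_row_count: int = 0
    inserted_count: int = 0
    updated_count: int = 0
    unchanged_count: int = 0
    load_time: datetime | None = None
    log: list[LoadLogEntry] = field(default_factory=list)
    # transient parsed rows; not persisted
    _raw_rows: list[dict] = field(default_factory=list, repr=False)
    _staged_rows: list[dict] = field(default_factory=list, repr=False)

    def add_log(self, level: str, message: str, row_ref: int | None = None) -> None:
        self.log.append(LoadLogEntry(level=level, message=message, row_ref=row_ref))

    def fatal_messages(self) -> list[str]:
        return [e.message for e in self.log if e.level == "fatal"]

    def check_conservation(self) -> None:
        if self.stage in ("STAGING", "LIVE") and self.staged_row_count + self.rejected_row_count != self.raw_row_count:
            raise AssertionError(f"{self.job_id}: staged+rejected != raw")
        if self.stage == "LIVE" and (
            self.inserted_count + self.updated_count + self.unchanged_count != self.staged_row_count
        ):
            raise AssertionError(f"{self.job_id}: inserted+updated+unchanged != staged")

    def summary(self) -> dict:
        return {
            "job_id": self.job_id,
            "dataset_id": self.dataset_id,
            "source_path": self.source_path,
            "file_digest": self.file_digest,
            "stage": self.stage,
            "raw": self.raw_row_count,
            "staged": self.staged_row_count,
            "rejected": self.rejected_row_count,
            "inserted": self.inserted_count,
            "updated": self.updated_count,
            "unchanged": self.unchanged_count,
            "load_time": self.load_time.isoformat() if self.load_time else None,
            "fatal": self.fatal_messages(),
        }

    def to_dict(self) -> dict:
        d = self.summary()
        d["started_at"] = self.started_at.isoformat()
        d["finished_at"] = self.finished_at.isoformat() if self.finished_at else None
        d["log"] = [e.to_dict() for e in self.log]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "LoadJob":
        job = cls(
            job_id=d["job_id"],
            dataset_id=d["dataset_id"],
            source_path=d["source_path"],
            file_digest=d["file_digest"],
            started_at=datetime.fromisoformat(d["started_at"]),
            finished_at=datetime.fromisoformat(d["finished_at"]) if d.get("finished_at") else None,
            stage=d["stage"],
            raw_row_count=d["raw"],
            staged_row_count=d["staged"],
            rejected_row_count=d["rejected"],
            inserted_count=d["inserted"],
            updated_count=d["updated"],
            unchanged_count=d["unchanged"],
            load_time=datetime.fromisoformat(d["load_time"]) if d.get("load_time") else None,
        )
        job.log = [LoadLogEntry.from_dict(e) for e in d.get("log", [])]
        return job


def _resolve_header(entry: CatalogueEntry, first_record: list[str]) -> list[str] | None:
    """Map a candidate header row to canonical column names, or None."""
    mapping = entry.load_logic.header_mapping
    known = set(entry.column_names())
    resolved = []
    for raw_name in first_record:
        name = raw_name.strip()
        canonical = mapping.get(name, name)
        if canonical not in known:
            return None
        resolved.append(canonical)
    if len(set(resolved)) != len(resolved):
        return None
    return resolved


def ingest_file(store: Store, dataset_ref: str, source_path: str) -> LoadJob:
    """Parse a feed file into a RAW job; digest the raw bytes with MD5."""
    entry = store.catalogue.resolve(dataset_ref)
    job = LoadJob(
        job_id=store.next_job_id(),
        dataset_id=entry.dataset_id,
        source_path=str(source_path),
        file_digest="",
        started_at=datetime.now(),
    )
    store.jobs.setdefault(entry.dataset_id, []).append(job)
    try:
        with open(source_path, "rb") as fh:
            raw_bytes = fh.read()
    except OSError as exc:
        raise LoadError(f"cannot read {source_path!r}: {exc}") from exc
    job.file_digest = hashlib.md5(raw_bytes).hexdigest()

    text = raw_bytes.decode("utf-8-sig")
    records = list(csv.reader(io.StringIO(text)))
    records = [r for r in records if r != []]
    if not records:
        job.add_log("warning", "empty file: no records")
        return job

    columns = _resolve_header(entry, records[0])
    if columns is not None:
        data_records = records[1:]
    elif entry.load_logic.headerless_column_order is not None:
        order = entry.load_logic.headerless_column_order
        if len(records[0]) != len(order):
            job.stage = "FAILED"
            job.add_log(
                "fatal",
                f"headerless file has {len(records[0])} fields, expected {len(order)}",
            )
            return job
        columns = list(order)
        data_records = records
    else:
        job.stage = "FAILED"
        job.add_log("fatal", f"unresolvable columns: header {records[0]!r} not recognised and no headerless order configured")
        return job

    rows = []
    for i, rec in enumerate(data_records):
        if len(rec) < len(columns):
            job.add_log("warning", f"short record padded with nulls ({len(rec)}/{len(columns)} fields)", row_ref=i)
            rec = rec + [""] * (len(columns) - len(rec))
        elif len(rec) > len(columns):
            job.add_log("warning", f"long record truncated ({len(rec)}/{len(columns)} fields)", row_ref=i)
            rec = rec[: len(columns)]
        rows.append(dict(zip(columns, rec)))
    job._raw_rows = rows
    job.raw_row_count = len(rows)
    if not rows:
        job.add_log("warning", "empty file: header only, no data rows")
    job.add_log("info", f"parsed {len(rows)} raw rows, digest {job.file_digest}")
    return job


def _clean_value(item, logic, raw: str | None) -> str | None:
    value: str | None = raw
    for step in logic.cleaning_steps:
        if value is None:
            break
        if step == "trim":
            value = value.strip()
        elif step == "null_tokens":
            if value in logic.null_tokens:
                value = None
        elif step == "parse_dates":
            if item.semantic_type == "date":
                for fmt in logic.date_formats:
                    try:
                        value = datetime.strptime(value, fmt).date().isoformat()
                        break
                    except ValueError:
                        continue
                # unparseable dates pass through verbatim; quality marks them wrong
        elif step == "uppercase_codes":
            if item.semantic_type == "code":
                value = value.upper()
    return value


def validate_and_stage(store: Store, job: LoadJob, *, reject_threshold: float | None = None) -> LoadJob:
    """Clean raw rows per the load logic and reject invalid ones."""
    if job.stage != "RAW":
        raise LoadError(f"job {job.job_id} is at {job.stage}, expected RAW")
    entry = store.catalogue.get(job.dataset_id)
    logic = entry.load_logic
    lookups = entry.lookup_map()
    threshold = store.reject_threshold if reject_threshold is None else reject_threshold

    staged: list[dict] = []
    rejected = 0
    seen_keys: set[tuple] = set()
    for i, raw_row in enumerate(job._raw_rows):
        row = {}
        for item in entry.items:
            row[item.column_name] = _clean_value(item, logic, raw_row.get(item.column_name))
        reject_reason = None
        key = tuple(row.get(c) for c in entry.primary_key)
        if entry.primary_key and any(v is None for v in key):
            reject_reason = "null primary key component"
        elif entry.primary_key and key in seen_keys:
            reject_reason = f"duplicate in-batch primary key {key!r}"
        else:
            for item in entry.items:
                for rule in item.validation_rules:
                    if rule.severity == "invalidates_row" and rule.violated_by(row[item.column_name], lookups):
                        reject_reason = (
                            f"column {item.column_name!r} violates {rule.rule_kind} rule"
                        )
                        break
                if reject_reason:
                    break
        if reject_reason:
            rejected += 1
            job.add_log("warning", f"row rejected: {reject_reason}", row_ref=i)
        else:
            if entry.primary_key:
                seen_keys.add(key)
            staged.append(row)

    job.staged_row_count = len(staged)
    job.rejected_row_count = rejected
    job._staged_rows = staged
    if job.raw_row_count and rejected / job.raw_row_count > threshold:
        job.stage = "FAILED"
        job.add_log(
            "fatal",
            f"rejected fraction {rejected}/{job.raw_row_count} exceeds threshold {threshold}",
        )
    else:
        job.stage = "STAGING"
        job.add_log("info", f"staged {len(staged)} rows, rejected {rejected}")
    job.check_conservation()
    return job


def merge_to_live(store: Store, job: LoadJob, load_time: datetime) -> LoadJob:
    """Upsert staged rows into live; archive superseded rows at load_time."""
    if job.stage != "STAGING":
        raise LoadError(f"job {job.job_id} is at {job.stage}, expected STAGING")
    entry = store.catalogue.get(job.dataset_id)
    if not entry.primary_key:
        raise LoadError(f"dataset {entry.name!r} has no primary key; cannot merge to live")
    last = store.last_load_time.get(job.dataset_id)
    if last is not None and load_time <= last:
        raise LoadError(
            f"load_time {load_time.isoformat()} not after previous load {last.isoformat()} (monotonic load clock)"
        )
    live, arch = store.dataset_state(job.dataset_id)
    inserted = updated = unchanged = 0
    for row in job._staged_rows:
        key = tuple(row[c] for c in entry.primary_key)
        existing = live.get(key)
        if existing is None:
            live[key] = LiveRecord(values=dict(row), valid_from=load_time)
            inserted += 1
        elif existing.values == row:
            unchanged += 1
        else:
            arch.append(
                ArchiveRecord(values=existing.values, valid_from=existing.valid_from, valid_to=load_time)
            )
            live[key] = LiveRecord(values=dict(row), valid_from=load_time)
            updated += 1
    job.inserted_count = inserted
    job.updated_count = updated
    job.unchanged_count = unchanged
    job.stage = "LIVE"
    job.load_time = load_time
    job.finished_at = datetime.now()
    store.last_load_time[job.dataset_id] = load_time
    job.add_log("info", f"live merge: inserted {inserted}, updated {updated}, unchanged {unchanged}")
    job.check_conservation()
    return job


def run_load(store: Store, dataset_ref: str, source_path: str, load_time: datetime | None = None) -> LoadJob:
    """Convenience: ingest, stage and merge one feed in a single call."""
    job = ingest_file(store, dataset_ref, source_path)
    if job.stage == "FAILED":
        return job
    validate_and_stage(store, job)
    if job.stage == "FAILED":
        return job
    if load_time is None:
        last = store.last_load_time.get(job.dataset_id)
        load_time = datetime.now()
        if last is not None and load_time <= last:
            load_time = last + timedelta(microseconds=1)
    return merge_to_live(store, job, load_time)


def tombstone(store: Store, dataset_ref: str, key_values: dict, load_time: datetime) -> bool:
    """Explicit delete mode: archive a live row without replacement.

    Returns True if a row was archived.  Source feeds never delete
    implicitly; this is the only way a primary key leaves the live table.
    """
    entry = store.catalogue.resolve(dataset_ref)
    last = store.last_load_time.get(entry.dataset_id)
    if last is not None and load_time <= last:
        raise LoadError("tombstone load_time must be after the latest load (monotonic load clock)")
    live, arch = store.dataset_state(entry.dataset_id)
    key = tuple(
        _clean_value(entry.item(c), entry.load_logic, key_values.get(c)) for c in entry.primary_key
    )
    existing = live.pop(key, None)
    if existing is None:
        return False
    arch.append(ArchiveRecord(values=existing.values, valid_from=existing.valid_from, valid_to=load_time))
    store.last_load_time[entry.dataset_id] = load_time
    return True


def get_load_history(store: Store, dataset_ref: str) -> list[dict]:
    """Job summaries for a dataset, in load order."""
    entry = store.catalogue.resolve(dataset_ref)
    return [job.summary() for job in store.jobs.get(entry.dataset_id, [])]


def _rows_to_frame(entry: CatalogueEntry, rows: list[dict]) -> pd.DataFrame:
    columns = entry.column_names()
    frame = pd.DataFrame(rows, columns=columns, dtype=object)
    if len(frame):
        frame = frame.sort_values(by=entry.primary_key or columns, kind="mergesort").reset_index(drop=True)
    return frame


def live_table(store: Store, dataset_ref: str) -> pd.DataFrame:
    """The current live rows as a DataFrame (string cells, None = null)."""
    entry = store.catalogue.resolve(dataset_ref)
    live, _ = store.dataset_state(entry.dataset_id)
    return _rows_to_frame(entry, [rec.values for rec in live.values()])


def reconstruct_as_at(store: Store, dataset_ref: str, t: datetime) -> pd.DataFrame:
    """The dataset exactly as it stood at time ``t``.

    Live rows with ``valid_from <= t`` plus archive rows whose validity
    interval covers ``t``; exactly one row per primary key that existed
    then.
    """
    entry = store.catalogue.resolve(dataset_ref)
    live, arch = store.dataset_state(entry.dataset_id)
    rows = [rec.values for rec in live.values() if rec.valid_from <= t]
    rows += [rec.values for rec in arch if rec.valid_from <= t < rec.valid_to]
    return _rows_to_frame(entry, rows)
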