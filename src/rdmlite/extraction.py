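"""The audited release pipeline: join, pseudonymise, govern, scan, bundle.

An extraction configuration names a committed cohort and, per dataset, the
columns and optional row filters to release.  The pipeline reconstructs
each dataset as at the configured instant (so refreshes reproduce byte-
identical files), restricts rows to cohort members, substitutes the
project's release identifier for the private one, then runs the
disclosure-control components in order:

1. **governance_filter** — removes Internal columns unconditionally and
   SpecialApprovalRequired columns without an approval (never vetoes);
2. **column_blacklister** — vetoes the whole release if any source column
   name matches a configured regular expression;
3. **chi_scanner** — vetoes if any cell contains a 10-digit window passing
   the CHI modulus-11 check (optionally redacting instead, never default).

A veto aborts the release: an audit with crash messages is persisted and
no bundle is written.  A successful run writes a release bundle directory
(data files, lookups, documents, extract-time quality report, release
metadata document, tailored branch catalogue, digest manifest).
"""

from __future__ import annotations

import csv
import hashlib
import json
import os
import re
from dataclasses import dataclass, field
from datetime import datetime

import pandas as pd

from .catalogue import Catalogue, CatalogueEntry
from .chi import ChiFinding, scan_for_chi
from .cohort import CommittedCohort, FilterContainer, describe_definition
from .errors import ExtractionError, ExtractionVetoed
from .load import reconstruct_as_at
from .quality import classify_rows
from .store import Store

DEFAULT_PIPELINE = ("governance_filter", "column_blacklister", "chi_scanner")
RELEASE_TYPES = ("First", "Refresh", "HICError", "ResearcherError", "ChangeRequest")

# the pipeline's own pseudonym column; exempt from blacklist matching
RELEASE_ID_COLUMN = "release_id"


@dataclass
class DatasetSelection:
    """Which columns (and optionally which rows) of one dataset to release."""

    dataset_id: str
    columns: list[str] | None = None  # None = all extractable columns
    row_filter: FilterContainer | None = None

    def to_dict(self) -> dict:
        return {
            "dataset_id": self.dataset_id,
            "columns": list(self.columns) if self.columns is not None else None,
            "row_filter": self.row_filter.to_dict() if self.row_filter else None,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DatasetSelection":
        return cls(
            dataset_id=d["dataset_id"],
            columns=list(d["columns"]) if d.get("columns") is not None else None,
            row_filter=FilterContainer.from_dict(d["row_filter"]) if d.get("row_filter") else None,
        )


@dataclass
class ExtractionConfiguration:
    config_id: str
    project_id: str
    cohort_id: str
    selections: list[DatasetSelection] = field(default_factory=list)
    special_approval_columns: dict = field(default_factory=dict)  # dataset_id -> [column]
    as_at: datetime | str = "live"
    blacklist_pattern: str | None = None
    pipeline_components: tuple = DEFAULT_PIPELINE
    redact: bool = False
    strict_chi_dates: bool = False
    release_type: str = "First"

    def __post_init__(self):
        if self.release_type not in RELEASE_TYPES:
            raise ExtractionError(f"unknown release type {self.release_type!r}")
        if self.blacklist_pattern is not None:
            if self.blacklist_pattern == "":
                raise ExtractionError("empty blacklist pattern rejected")
            try:
                re.compile(self.blacklist_pattern)
            except re.error as exc:
                raise ExtractionError(f"blacklist pattern does not compile: {exc}") from exc
        for comp in self.pipeline_components:
            if comp not in DEFAULT_PIPELINE:
                raise ExtractionError(f"unknown pipeline component {comp!r}")

    def approved(self, dataset_id: str) -> set:
        return set(self.special_approval_columns.get(dataset_id, ()))

    def to_dict(self) -> dict:
        return {
            "config_id": self.config_id,
            "project_id": self.project_id,
            "cohort_id": self.cohort_id,
            "selections": [s.to_dict() for s in self.selections],
            "special_approval_columns": {k: list(v) for k, v in self.special_approval_columns.items()},
            "as_at": self.as_at.isoformat() if isinstance(self.as_at, datetime) else self.as_at,
            "blacklist_pattern": self.blacklist_pattern,
            "pipeline_components": list(self.pipeline_components),
            "redact": self.redact,
            "strict_chi_dates": self.strict_chi_dates,
            "release_type": self.release_type,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ExtractionConfiguration":
        as_at = d.get("as_at", "live")
        if as_at != "live":
            as_at = datetime.fromisoformat(as_at)
        return cls(
            config_id=d["config_id"],
            project_id=d["project_id"],
            cohort_id=d["cohort_id"],
            selections=[DatasetSelection.from_dict(s) for s in d.get("selections", [])],
            special_approval_columns={k: list(v) for k, v in d.get("special_approval_columns", {}).items()},
            as_at=as_at,
            blacklist_pattern=d.get("blacklist_pattern"),
            pipeline_components=tuple(d.get("pipeline_components", DEFAULT_PIPELINE)),
            redact=d.get("redact", False),
            strict_chi_dates=d.get("strict_chi_dates", False),
            release_type=d.get("release_type", "First"),
        )


@dataclass
class ReleaseAudit:
    release_id: str
    config_id: str
    cohort_id: str
    cohort_version: int
    started_at: str
    as_at_effective: str
    release_type: str
    rows_created: dict = field(default_factory=dict)  # dataset name -> rows
    crash_messages: list = field(default_factory=list)
    governance_removals: dict = field(default_factory=dict)  # dataset name -> [column]
    succeeded: bool = False

    def to_dict(self) -> dict:
        return {
            "release_id": self.release_id,
            "config_id": self.config_id,
            "cohort_id": self.cohort_id,
            "cohort_version": self.cohort_version,
            "started_at": self.started_at,
            "as_at_effective": self.as_at_effective,
            "release_type": self.release_type,
            "rows_created": dict(self.rows_created),
            "crash_messages": list(self.crash_messages),
            "governance_removals": {k: list(v) for k, v in self.governance_removals.items()},
            "succeeded": self.succeeded,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ReleaseAudit":
        return cls(**d)


@dataclass
class ReleaseBundle:
    """The on-disk artefact a researcher receives."""

    release_id: str
    path: str
    data_files: dict  # dataset name -> relative path
    frames: dict  # dataset name -> DataFrame (as released)
    manifest: dict

    def file_path(self, relative: str) -> str:
        return os.path.join(self.path, relative)


# -- pipeline components --------------------------------------------------


def governance_filter(
    table: pd.DataFrame, entry: CatalogueEntry, approved: set
) -> tuple[pd.DataFrame, list[str]]:
    """Drop Internal and unapproved SpecialApprovalRequired columns.

    Always succeeds; returns the filtered table and the removed names.
    """
    removed = []
    keep = []
    for col in table.columns:
        if col == RELEASE_ID_COLUMN or not entry.has_column(col):
            keep.append(col)
            continue
        category = entry.item(col).extraction_category
        if category == "Internal":
            removed.append(col)
        elif category == "SpecialApprovalRequired" and col not in approved:
            removed.append(col)
        else:
            keep.append(col)
    return table[keep], removed


def column_blacklister(table: pd.DataFrame, pattern: str) -> pd.DataFrame:
    """Pass the table through unless a column name matches the pattern.

    Matching is case-insensitive substring search; the pipeline's own
    release-identifier column is exempt.  A match raises
    :class:`ExtractionVetoed`.
    """
    if not pattern:
        raise ExtractionError("empty blacklist pattern rejected")
    rx = re.compile(pattern, re.IGNORECASE)
    offending = [c for c in table.columns if c != RELEASE_ID_COLUMN and rx.search(c)]
    if offending:
        raise ExtractionVetoed(f"blacklisted column name(s): {', '.join(offending)}")
    return table


def chi_scanner(
    table: pd.DataFrame, dataset_id: str, *, redact: bool = False, strict_date: bool = False
) -> tuple[pd.DataFrame, list[ChiFinding]]:
    """Scan all cells for CHI-like numbers; veto (or redact) on findings."""
    findings = scan_for_chi(table, dataset_id, strict_date=strict_date)
    if findings and not redact:
        raise ExtractionVetoed(
            f"{len(findings)} CHI-like number(s) found in dataset {dataset_id}", findings=findings
        )
    if findings and redact:
        table = table.copy()
        for f in findings:
            col = f.column
            table[col] = table[col].map(
                lambda v: v if v is None else str(v).replace(f.matched, "X" * 10)
            )
    return table, findings


# -- extraction -----------------------------------------------------------


def _validate_config(store: Store, config: ExtractionConfiguration, cohort: CommittedCohort) -> None:
    if cohort.project_id != config.project_id:
        raise ExtractionError(
            f"cohort {config.cohort_id} belongs to project {cohort.project_id!r}, not {config.project_id!r}"
        )
    if not config.selections:
        raise ExtractionError("configuration selects no datasets")
    seen = set()
    for sel in config.selections:
        if sel.dataset_id in seen:
            raise ExtractionError(f"dataset {sel.dataset_id} selected twice")
        seen.add(sel.dataset_id)
        entry = store.catalogue.get(sel.dataset_id)
        if entry.identifier_column() is None:
            raise ExtractionError(f"dataset {entry.name!r} has no identifier column; cannot link")
        approved = config.approved(sel.dataset_id)
        for col in approved:
            if not entry.has_column(col):
                raise ExtractionError(f"approval names unknown column {entry.name}.{col}")
        if sel.columns is not None:
            for col in sel.columns:
                if not entry.has_column(col):
                    raise ExtractionError(f"selection names unknown column {entry.name}.{col}")
                item = entry.item(col)
                if item.extraction_category == "Internal":
                    raise ExtractionError(f"selection may not include Internal column {entry.name}.{col}")
                if item.extraction_category == "SpecialApprovalRequired" and col not in approved:
                    raise ExtractionError(
                        f"column {entry.name}.{col} requires special approval; none granted"
                    )


def _selected_columns(entry: CatalogueEntry, sel: DatasetSelection, approved: set) -> list[str]:
    """Columns entering the pipeline; the governance filter still runs after.

    The default (all-columns) selection keeps unapproved special-approval
    columns here so that their removal happens in — and is logged by — the
    governance component rather than silently at selection time.
    """
    if sel.columns is not None:
        return list(sel.columns)
    return [item.column_name for item in entry.items if item.extraction_category != "Internal"]


def _extract_dataset(
    store: Store,
    config: ExtractionConfiguration,
    sel: DatasetSelection,
    cohort: CommittedCohort,
    as_at: datetime,
    audit: ReleaseAudit,
) -> pd.DataFrame:
    entry = store.catalogue.get(sel.dataset_id)
    id_col = entry.identifier_column()
    table = reconstruct_as_at(store, entry.dataset_id, as_at)

    rows = []
    for _, row in table.iterrows():
        rowd = {c: row[c] for c in table.columns}
        ident = rowd.get(id_col)
        if ident not in cohort.members:
            continue
        if sel.row_filter is not None and not sel.row_filter.row_satisfies(rowd):
            continue
        rowd[RELEASE_ID_COLUMN] = cohort.release_map[ident]
        rows.append(rowd)

    columns = [RELEASE_ID_COLUMN] + _selected_columns(entry, sel, config.approved(sel.dataset_id))
    frame = pd.DataFrame(rows, columns=[RELEASE_ID_COLUMN] + entry.column_names(), dtype=object)
    sort_cols = [RELEASE_ID_COLUMN] + (entry.primary_key or [])
    if len(frame):
        frame = frame.sort_values(by=sort_cols, kind="mergesort").reset_index(drop=True)
    frame = frame[columns]

    for component in config.pipeline_components:
        if component == "governance_filter":
            frame, removed = governance_filter(frame, entry, config.approved(sel.dataset_id))
            if removed:
                audit.governance_removals[entry.name] = removed
        elif component == "column_blacklister" and config.blacklist_pattern:
            frame = column_blacklister(frame, config.blacklist_pattern)
        elif component == "chi_scanner":
            frame, _ = chi_scanner(
                frame, entry.dataset_id, redact=config.redact, strict_date=config.strict_chi_dates
            )
    return frame


def _write_csv(path: str, frame: pd.DataFrame) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(list(frame.columns))
        for _, row in frame.iterrows():
            writer.writerow(["" if row[c] is None else str(row[c]) for c in frame.columns])


def _digests(path: str) -> dict:
    with open(path, "rb") as fh:
        data = fh.read()
    return {"sha256": hashlib.sha256(data).hexdigest(), "md5": hashlib.md5(data).hexdigest()}


def generate_branch_catalogue(store: Store, config: ExtractionConfiguration) -> dict:
    """Portable catalogue restricted to the extracted datasets and columns.

    Private-identifier (Internal) items are omitted; primary keys and the
    event-date column are restricted to surviving columns so the document
    re-imports cleanly on a branch node.
    """
    branch = Catalogue()
    for sel in config.selections:
        entry = store.catalogue.get(sel.dataset_id)
        approved = config.approved(sel.dataset_id)
        keep = set(_selected_columns(entry, sel, approved))
        doc = entry.to_dict()
        doc["items"] = [i for i in doc["items"] if i["column_name"] in keep]
        doc["primary_key"] = [c for c in doc["primary_key"] if c in keep]
        if doc["event_date_column"] not in keep:
            doc["event_date_column"] = None
        mapping = doc["load_logic"]["header_mapping"]
        doc["load_logic"]["header_mapping"] = {a: c for a, c in mapping.items() if c in keep}
        order = doc["load_logic"]["headerless_column_order"]
        if order:
            doc["load_logic"]["headerless_column_order"] = [c for c in order if c in keep]
        from .catalogue import CatalogueEntry as CE

        branch._entries[doc["dataset_id"]] = CE.from_dict(doc)
    return branch.export_document()


def generate_release_document(
    store: Store, config: ExtractionConfiguration, cohort: CommittedCohort, frames: dict
) -> str:
    """Markdown metadata document covering exactly the extracted fields.

    Deterministic given the configuration and bundle contents: catalogue
    descriptions per selected column, the cohort logic rendering, and
    per-dataset monthly record counts of the extracted rows.
    """
    lines = [
        f"# Release metadata — configuration {config.config_id}",
        "",
        f"* Project: {config.project_id}",
        f"* Cohort: {cohort.cohort_id} (definition {cohort.definition_id}, version {cohort.version})",
        f"* As at: {config.as_at.isoformat() if isinstance(config.as_at, datetime) else config.as_at}",
        f"* Release type: {config.release_type}",
        "",
        "## Extracted fields",
        "",
    ]
    for sel in config.selections:
        entry = store.catalogue.get(sel.dataset_id)
        frame = frames[entry.name]
        lines.append(f"### {entry.name} ({entry.dataset_id})")
        if entry.description:
            lines.append(f"\n{entry.description}\n")
        lines.append("")
        lines.append("| column | type | description |")
        lines.append("|---|---|---|")
        for col in frame.columns:
            if col == RELEASE_ID_COLUMN:
                lines.append(f"| {col} | text | project release identifier (pseudonym) |")
                continue
            item = entry.item(col)
            lines.append(f"| {col} | {item.semantic_type} | {item.description or '—'} |")
        lines.append("")
        if entry.event_date_column and entry.event_date_column in frame.columns:
            months: dict[str, int] = {}
            for value in frame[entry.event_date_column]:
                month = str(value)[:7] if value is not None else "undated"
                months[month] = months.get(month, 0) + 1
            lines.append("Monthly record counts:")
            lines.append("")
            for month in sorted(months):
                lines.append(f"* {month}: {months[month]}")
            lines.append("")
        else:
            lines.append(f"Records extracted: {len(frame)}")
            lines.append("")
    definition = store.definitions.get(cohort.definition_id)
    lines.append("## Cohort logic")
    lines.append("")
    lines.append("```")
    if definition is not None:
        lines.append(describe_definition(definition, store.catalogue).rstrip("\n"))
    else:
        lines.append(f"(definition {cohort.definition_id} not on this node)")
    lines.append("```")
    lines.append("")
    return "\n".join(lines)


def run_extraction(
    store: Store,
    config: ExtractionConfiguration,
    out_dir: str,
    *,
    now: datetime | None = None,
) -> tuple[ReleaseBundle, ReleaseAudit]:
    """Execute the full release pipeline for one configuration.

    Returns the bundle and its audit.  On a disclosure veto the audit is
    persisted with crash messages, nothing is written to disk, and
    :class:`ExtractionVetoed` (carrying the audit) is raised.
    """
    try:
        cohort = store.cohorts[config.cohort_id]
    except KeyError:
        raise ExtractionError(f"unknown cohort {config.cohort_id!r}") from None
    _validate_config(store, config, cohort)
    now = now or datetime.now()
    as_at = now if config.as_at == "live" else config.as_at

    audit = ReleaseAudit(
        release_id=store.next_release_id(),
        config_id=config.config_id,
        cohort_id=config.cohort_id,
        cohort_version=cohort.version,
        started_at=now.isoformat(),
        as_at_effective=as_at.isoformat(),
        release_type=config.release_type,
    )
    store.audits.append(audit)

    frames: dict[str, pd.DataFrame] = {}
    try:
        for sel in config.selections:
            entry = store.catalogue.get(sel.dataset_id)
            frame = _extract_dataset(store, config, sel, cohort, as_at, audit)
            frames[entry.name] = frame
            audit.rows_created[entry.name] = len(frame)
    except ExtractionVetoed as veto:
        audit.crash_messages.append(str(veto))
        veto.audit = audit
        raise

    bundle_dir = os.path.join(out_dir, audit.release_id)
    os.makedirs(os.path.join(bundle_dir, "data"), exist_ok=True)
    os.makedirs(os.path.join(bundle_dir, "lookups"), exist_ok=True)
    os.makedirs(os.path.join(bundle_dir, "docs"), exist_ok=True)

    data_files = {}
    for sel in config.selections:
        entry = store.catalogue.get(sel.dataset_id)
        rel = os.path.join("data", f"{entry.name}.csv")
        _write_csv(os.path.join(bundle_dir, rel), frames[entry.name])
        data_files[entry.name] = rel

    lookup_files = []
    for sel in config.selections:
        entry = store.catalogue.get(sel.dataset_id)
        for col in frames[entry.name].columns:
            if col == RELEASE_ID_COLUMN:
                continue
            item = entry.item(col)
            if item.lookup is None:
                continue
            rel = os.path.join("lookups", f"{item.lookup.lookup_id}.csv")
            full = os.path.join(bundle_dir, rel)
            if not os.path.exists(full):
                with open(full, "w", encoding="utf-8", newline="") as fh:
                    writer = csv.writer(fh)
                    writer.writerow([item.lookup.code_column, item.lookup.description_column])
                    for code in sorted(item.lookup.rows):
                        writer.writerow([code, item.lookup.rows[code]])
                lookup_files.append(rel)

    doc_files = []
    seen_docs = set()
    for sel in config.selections:
        entry = store.catalogue.get(sel.dataset_id)
        for doc in entry.documents:
            if doc.global_flag and doc.doc_id not in seen_docs:
                seen_docs.add(doc.doc_id)
                rel = os.path.join("docs", f"{doc.doc_id}.md")
                with open(os.path.join(bundle_dir, rel), "w", encoding="utf-8") as fh:
                    fh.write(f"# {doc.title}\n\n{doc.body}\n")
                doc_files.append(rel)

    # extract-time quality report, computed on the released rows only
    quality = {}
    for sel in config.selections:
        entry = store.catalogue.get(sel.dataset_id)
        frame = frames[entry.name]
        rows = [dict(zip(frame.columns, r)) for r in frame.itertuples(index=False, name=None)]
        cols = [c for c in frame.columns if c != RELEASE_ID_COLUMN]
        per_column, per_period = classify_rows(entry, rows, cols)
        quality[entry.name] = {
            "row_count": len(rows),
            "per_column": per_column,
            "per_period": per_period,
        }
    with open(os.path.join(bundle_dir, "quality_report.json"), "w", encoding="utf-8") as fh:
        json.dump(quality, fh, indent=1, sort_keys=True)

    release_doc = generate_release_document(store, config, cohort, frames)
    with open(os.path.join(bundle_dir, "docs", "release_document.md"), "w", encoding="utf-8") as fh:
        fh.write(release_doc)
    doc_files.append(os.path.join("docs", "release_document.md"))

    branch_doc = generate_branch_catalogue(store, config)
    with open(os.path.join(bundle_dir, "catalogue.json"), "w", encoding="utf-8") as fh:
        json.dump(branch_doc, fh, indent=1, sort_keys=True)

    manifest_files = sorted(
        list(data_files.values()) + lookup_files + doc_files + ["quality_report.json", "catalogue.json"]
    )
    manifest = {
        "release_id": audit.release_id,
        "files": {rel: _digests(os.path.join(bundle_dir, rel)) for rel in manifest_files},
    }
    with open(os.path.join(bundle_dir, "manifest.json"), "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)

    audit.succeeded = True
    bundle = ReleaseBundle(
        release_id=audit.release_id,
        path=bundle_dir,
        data_files=data_files,
        frames=frames,
        manifest=manifest,
    )
    return bundle, audit
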