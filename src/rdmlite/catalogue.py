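"""Dataset catalogue: the metadata inventory that drives every other process.

The catalogue holds one :class:`CatalogueEntry` per dataset — column-level
metadata, validation rules, load logic, lookups, issues and supporting
documents.  It is the single source of truth consulted by the load engine
(cleaning and header resolution), the quality process (rule conformance),
the cohort builder (identifier column) and the extraction pipeline
(governance tiers).

A catalogue exports to a self-contained portable JSON document and imports
back losslessly, which is how a project ("branch") node receives a tailored
copy and how researcher contributions are merged back into the root.
"""

from __future__ import annotations

import copy
import re
from dataclasses import dataclass, field
from datetime import date, datetime, timezone

from .errors import CatalogueError, UnknownColumnError, UnknownDatasetError

SCHEMA_VERSION = 1

SEMANTIC_TYPES = ("text", "integer", "decimal", "date", "code")
EXTRACTION_CATEGORIES = ("Core", "Supplemental", "SpecialApprovalRequired", "Internal")
RULE_KINDS = ("not_null", "regex", "bounds", "lookup_membership", "date_range")
SEVERITIES = ("missing", "wrong", "invalidates_row")

DEFAULT_NULL_TOKENS = ("", "NULL", "NA")
DEFAULT_DATE_FORMATS = ("%Y-%m-%d", "%d/%m/%Y")
CLEANING_STEPS = ("trim", "null_tokens", "parse_dates", "uppercase_codes")


def utcnow_iso() -> str:
    return datetime.now(timezone.utc).replace(microsecond=0).isoformat()


def parse_iso_date(value: str) -> date | None:
    try:
        return date.fromisoformat(value)
    except (ValueError, TypeError):
        return None


@dataclass
class ValidationRuleSpec:
    """One declarative validation rule attached to a catalogue item.

    ``severity`` controls what a violation means downstream: ``missing`` and
    ``wrong`` drive quality classification only; ``invalidates_row`` causes
    the load engine to reject the whole row at staging.
    """

    rule_kind: str
    params: dict = field(default_factory=dict)
    severity: str = "wrong"

    def __post_init__(self):
        if self.rule_kind not in RULE_KINDS:
            raise CatalogueError(f"unknown rule kind {self.rule_kind!r}")
        if self.severity not in SEVERITIES:
            raise CatalogueError(f"unknown severity {self.severity!r}")
        if self.rule_kind == "regex":
            pattern = self.params.get("pattern")
            if not pattern:
                raise CatalogueError("regex rule requires a 'pattern' param")
            try:
                re.compile(pattern)
            except re.error as exc:
                raise CatalogueError(f"regex rule does not compile: {exc}") from exc
        elif self.rule_kind == "bounds":
            try:
                lower = float(self.params["lower"])
                upper = float(self.params["upper"])
            except (KeyError, TypeError, ValueError) as exc:
                raise CatalogueError("bounds rule requires numeric lower/upper") from exc
            if lower > upper:
                raise CatalogueError("bounds rule requires lower <= upper")
        elif self.rule_kind == "lookup_membership":
            if not self.params.get("lookup_id"):
                raise CatalogueError("lookup_membership rule requires 'lookup_id'")
        elif self.rule_kind == "date_range":
            earliest = self.params.get("earliest")
            latest = self.params.get("latest")
            for bound in (earliest, latest):
                if bound is not None and parse_iso_date(bound) is None:
                    raise CatalogueError("date_range bounds must be ISO dates")
            if earliest and latest and earliest > latest:
                raise CatalogueError("date_range requires earliest <= latest")

    def violated_by(self, value: str | None, lookups: dict[str, "LookupRef"]) -> bool:
        """True iff a cleaned cell value violates this rule.

        A null value violates only ``not_null``; missingness of non-null
        rules is classified separately by the quality process.
        """
        if self.rule_kind == "not_null":
            return value is None
        if value is None:
            return False
        if self.rule_kind == "regex":
            return re.fullmatch(self.params["pattern"], value) is None
        if self.rule_kind == "bounds":
            try:
                v = float(value)
            except ValueError:
                return True
            return not (float(self.params["lower"]) <= v <= float(self.params["upper"]))
        if self.rule_kind == "lookup_membership":
            lookup = lookups.get(self.params["lookup_id"])
            if lookup is None:
                return True
            return value not in lookup.rows
        if self.rule_kind == "date_range":
            d = parse_iso_date(value)
            if d is None:
                return True
            earliest = self.params.get("earliest")
            latest = self.params.get("latest")
            if earliest and value < earliest:
                return True
            if latest and value > latest:
                return True
            return False
        raise AssertionError(self.rule_kind)

    def to_dict(self) -> dict:
        return {"rule_kind": self.rule_kind, "params": dict(self.params), "severity": self.severity}

    @classmethod
    def from_dict(cls, d: dict) -> "ValidationRuleSpec":
        return cls(rule_kind=d["rule_kind"], params=dict(d.get("params", {})), severity=d.get("severity", "wrong"))


@dataclass
class LookupRef:
    """A code → description table referenced by coded columns."""

    lookup_id: str
    rows: dict[str, str] = field(default_factory=dict)
    code_column: str = "code"
    description_column: str = "description"

    def to_dict(self) -> dict:
        return {
            "lookup_id": self.lookup_id,
            "code_column": self.code_column,
            "description_column": self.description_column,
            "rows": dict(self.rows),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LookupRef":
        return cls(
            lookup_id=d["lookup_id"],
            rows=dict(d.get("rows", {})),
            code_column=d.get("code_column", "code"),
            description_column=d.get("description_column", "description"),
        )


@dataclass
class DatasetIssue:
    issue_id: str
    text: str
    status: str = "open"
    created_at: str = field(default_factory=utcnow_iso)

    def to_dict(self) -> dict:
        return {"issue_id": self.issue_id, "text": self.text, "status": self.status, "created_at": self.created_at}

    @classmethod
    def from_dict(cls, d: dict) -> "DatasetIssue":
        return cls(**d)


@dataclass
class SupportingDocument:
    doc_id: str
    title: str
    body: str = ""
    global_flag: bool = False

    def to_dict(self) -> dict:
        return {"doc_id": self.doc_id, "title": self.title, "body": self.body, "global_flag": self.global_flag}

    @classmethod
    def from_dict(cls, d: dict) -> "SupportingDocument":
        return cls(**d)


@dataclass
class LoadLogicSpec:
    """How raw feed files for a dataset are parsed and cleaned.

    ``header_mapping`` translates renamed source headers to canonical column
    names; ``headerless_column_order`` resolves files whose first record is
    not a recognisable header.  ``cleaning_steps`` run in list order.
    """

    header_mapping: dict[str, str] = field(default_factory=dict)
    headerless_column_order: list[str] | None = None
    cleaning_steps: list[str] = field(default_factory=lambda: list(CLEANING_STEPS))
    null_tokens: list[str] = field(default_factory=lambda: list(DEFAULT_NULL_TOKENS))
    date_formats: list[str] = field(default_factory=lambda: list(DEFAULT_DATE_FORMATS))

    def __post_init__(self):
        for step in self.cleaning_steps:
            if step not in CLEANING_STEPS:
                raise CatalogueError(f"unknown cleaning step {step!r}")

    def to_dict(self) -> dict:
        return {
            "header_mapping": dict(self.header_mapping),
            "headerless_column_order": list(self.headerless_column_order) if self.headerless_column_order else None,
            "cleaning_steps": list(self.cleaning_steps),
            "null_tokens": list(self.null_tokens),
            "date_formats": list(self.date_formats),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LoadLogicSpec":
        return cls(
            header_mapping=dict(d.get("header_mapping", {})),
            headerless_column_order=list(d["headerless_column_order"]) if d.get("headerless_column_order") else None,
            cleaning_steps=list(d.get("cleaning_steps", CLEANING_STEPS)),
            null_tokens=list(d.get("null_tokens", DEFAULT_NULL_TOKENS)),
            date_formats=list(d.get("date_formats", DEFAULT_DATE_FORMATS)),
        )


@dataclass
class CatalogueItem:
    """Per-column metadata: description, governance tier, rules, lookup.

    ``extraction_category`` is the governance tier: Core and Supplemental
    columns extract freely, SpecialApprovalRequired columns only when the
    extraction configuration carries an approval, Internal columns never.
    ``role`` marks the dataset's private-identifier column ("identifier"),
    which must be an Internal item.
    """

    column_name: str
    description: str = ""
    semantic_type: str = "text"
    extraction_category: str = "Core"
    validation_rules: list[ValidationRuleSpec] = field(default_factory=list)
    lookup: LookupRef | None = None
    role: str | None = None

    def __post_init__(self):
        if self.semantic_type not in SEMANTIC_TYPES:
            raise CatalogueError(f"unknown semantic type {self.semantic_type!r}")
        if self.extraction_category not in EXTRACTION_CATEGORIES:
            raise CatalogueError(f"unknown extraction category {self.extraction_category!r}")
        if self.role not in (None, "identifier"):
            raise CatalogueError(f"unknown item role {self.role!r}")

    def to_dict(self) -> dict:
        return {
            "column_name": self.column_name,
            "description": self.description,
            "semantic_type": self.semantic_type,
            "extraction_category": self.extraction_category,
            "validation_rules": [r.to_dict() for r in self.validation_rules],
            "lookup": self.lookup.to_dict() if self.lookup else None,
            "role": self.role,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CatalogueItem":
        return cls(
            column_name=d["column_name"],
            description=d.get("description", ""),
            semantic_type=d.get("semantic_type", "text"),
            extraction_category=d.get("extraction_category", "Core"),
            validation_rules=[ValidationRuleSpec.from_dict(r) for r in d.get("validation_rules", [])],
            lookup=LookupRef.from_dict(d["lookup"]) if d.get("lookup") else None,
            role=d.get("role"),
        )


@dataclass
class CatalogueEntry:
    """All metadata for one dataset."""

    dataset_id: str
    name: str
    description: str = ""
    primary_key: list[str] = field(default_factory=list)
    event_date_column: str | None = None
    items: list[CatalogueItem] = field(default_factory=list)
    load_logic: LoadLogicSpec = field(default_factory=LoadLogicSpec)
    issues: list[DatasetIssue] = field(default_factory=list)
    documents: list[SupportingDocument] = field(default_factory=list)
    lookups: list[LookupRef] = field(default_factory=list)
    change_log: list[dict] = field(default_factory=list)

    def column_names(self) -> list[str]:
        return [it.column_name for it in self.items]

    def item(self, column_name: str) -> CatalogueItem:
        for it in self.items:
            if it.column_name == column_name:
                return it
        raise UnknownColumnError(f"dataset {self.name!r} has no column {column_name!r}")

    def has_column(self, column_name: str) -> bool:
        return any(it.column_name == column_name for it in self.items)

    def identifier_column(self) -> str | None:
        """The column flagged role=identifier (the private patient identifier)."""
        for it in self.items:
            if it.role == "identifier":
                return it.column_name
        return None

    def lookup_map(self) -> dict[str, LookupRef]:
        return {lk.lookup_id: lk for lk in self.lookups}

    def validate(self) -> None:
        names = self.column_names()
        if len(set(names)) != len(names):
            raise CatalogueError(f"dataset {self.name!r}: duplicate column names")
        for pk in self.primary_key:
            if pk not in names:
                raise CatalogueError(f"dataset {self.name!r}: primary key column {pk!r} unknown")
        if self.event_date_column is not None and self.event_date_column not in names:
            raise CatalogueError(f"dataset {self.name!r}: event date column {self.event_date_column!r} unknown")
        for canonical in self.load_logic.header_mapping.values():
            if canonical not in names:
                raise CatalogueError(f"dataset {self.name!r}: header mapping targets unknown column {canonical!r}")
        ident = [it for it in self.items if it.role == "identifier"]
        for it in ident:
            if it.extraction_category != "Internal":
                raise CatalogueError(f"dataset {self.name!r}: identifier column {it.column_name!r} must be Internal")
        if len(ident) > 1:
            raise CatalogueError(f"dataset {self.name!r}: more than one identifier column")

    def to_dict(self) -> dict:
        return {
            "dataset_id": self.dataset_id,
            "name": self.name,
            "description": self.description,
            "primary_key": list(self.primary_key),
            "event_date_column": self.event_date_column,
            "items": [it.to_dict() for it in self.items],
            "load_logic": self.load_logic.to_dict(),
            "issues": [i.to_dict() for i in self.issues],
            "documents": [d.to_dict() for d in self.documents],
            "lookups": [lk.to_dict() for lk in self.lookups],
            "change_log": copy.deepcopy(self.change_log),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CatalogueEntry":
        entry = cls(
            dataset_id=d["dataset_id"],
            name=d["name"],
            description=d.get("description", ""),
            primary_key=list(d.get("primary_key", [])),
            event_date_column=d.get("event_date_column"),
            items=[CatalogueItem.from_dict(i) for i in d.get("items", [])],
            load_logic=LoadLogicSpec.from_dict(d.get("load_logic", {})),
            issues=[DatasetIssue.from_dict(i) for i in d.get("issues", [])],
            documents=[SupportingDocument.from_dict(x) for x in d.get("documents", [])],
            lookups=[LookupRef.from_dict(x) for x in d.get("lookups", [])],
            change_log=copy.deepcopy(d.get("change_log", [])),
        )
        entry.validate()
        return entry


@dataclass
class MergeReport:
    """Outcome of merging a branch catalogue document into a root catalogue."""

    additions: list[str] = field(default_factory=list)
    conflicts: list[str] = field(default_factory=list)
    unknown_datasets: list[str] = field(default_factory=list)
    unknown_columns: list[str] = field(default_factory=list)

    @property
    def n_additions(self) -> int:
        return len(self.additions)

    @property
    def n_conflicts(self) -> int:
        return len(self.conflicts)

    def to_dict(self) -> dict:
        return {
            "additions": list(self.additions),
            "conflicts": list(self.conflicts),
            "unknown_datasets": list(self.unknown_datasets),
            "unknown_columns": list(self.unknown_columns),
        }


class Catalogue:
    """An inventory of dataset metadata, keyed by fresh dataset ids."""

    def __init__(self):
        self._entries: dict[str, CatalogueEntry] = {}
        self._counter = 0

    def __len__(self) -> int:
        return len(self._entries)

    def entries(self) -> list[CatalogueEntry]:
        return [self._entries[k] for k in sorted(self._entries)]

    def dataset_ids(self) -> list[str]:
        return sorted(self._entries)

    def get(self, dataset_id: str) -> CatalogueEntry:
        try:
            return self._entries[dataset_id]
        except KeyError:
            raise UnknownDatasetError(f"unknown dataset id {dataset_id!r}") from None

    def by_name(self, name: str) -> CatalogueEntry | None:
        for entry in self._entries.values():
            if entry.name == name:
                return entry
        return None

    def resolve(self, ref: str) -> CatalogueEntry:
        """Accept either a dataset id or a dataset name."""
        if ref in self._entries:
            return self._entries[ref]
        entry = self.by_name(ref)
        if entry is None:
            raise UnknownDatasetError(f"unknown dataset {ref!r}")
        return entry

    def _fresh_id(self) -> str:
        while True:
            candidate = f"ds{self._counter:04d}"
            self._counter += 1
            if candidate not in self._entries:
                return candidate

    # -- operations -------------------------------------------------------

    def register_dataset(
        self,
        name: str,
        columns: list[tuple[str, str]],
        primary_key: list[str] | None = None,
        *,
        description: str = "",
        event_date_column: str | None = None,
    ) -> CatalogueEntry:
        """Register a new dataset; all items default to Core with no rules."""
        if not name:
            raise CatalogueError("dataset name must be non-empty")
        if not columns:
            raise CatalogueError("dataset must have at least one column")
        if self.by_name(name) is not None:
            raise CatalogueError(f"dataset name {name!r} already registered")
        primary_key = list(primary_key or [])
        items = [CatalogueItem(column_name=c, semantic_type=t) for c, t in columns]
        entry = CatalogueEntry(
            dataset_id=self._fresh_id(),
            name=name,
            description=description,
            primary_key=primary_key,
            event_date_column=event_date_column,
            items=items,
        )
        entry.validate()
        self._entries[entry.dataset_id] = entry
        return entry

    def set_column_metadata(
        self,
        dataset_ref: str,
        column_name: str,
        *,
        description: str | None = None,
        category: str | None = None,
        role: str | None = None,
        at: str | None = None,
    ) -> CatalogueItem:
        entry = self.resolve(dataset_ref)
        item = entry.item(column_name)
        changed = []
        if description is not None and description != item.description:
            item.description = description
            changed.append("description")
        if category is not None and category != item.extraction_category:
            if category not in EXTRACTION_CATEGORIES:
                raise CatalogueError(f"unknown extraction category {category!r}")
            item.extraction_category = category
            changed.append("extraction_category")
        if role is not None and role != item.role:
            if role not in ("identifier",):
                raise CatalogueError(f"unknown item role {role!r}")
            item.role = role
            changed.append("role")
        if changed:
            entry.change_log.append(
                {"at": at or utcnow_iso(), "column": column_name, "changed": changed}
            )
            entry.validate()
        return item

    def attach_validation_rule(
        self, dataset_ref: str, column_name: str, rule: ValidationRuleSpec
    ) -> CatalogueItem:
        entry = self.resolve(dataset_ref)
        item = entry.item(column_name)
        if rule.rule_kind == "lookup_membership" and rule.params["lookup_id"] not in entry.lookup_map():
            raise CatalogueError(
                f"lookup {rule.params['lookup_id']!r} not registered on dataset {entry.name!r}"
            )
        item.validation_rules.append(rule)
        return item

    def add_lookup(self, dataset_ref: str, lookup: LookupRef) -> LookupRef:
        entry = self.resolve(dataset_ref)
        if lookup.lookup_id in entry.lookup_map():
            raise CatalogueError(f"lookup {lookup.lookup_id!r} already attached")
        entry.lookups.append(lookup)
        return lookup

    def add_document(self, dataset_ref: str, doc: SupportingDocument) -> SupportingDocument:
        entry = self.resolve(dataset_ref)
        if any(d.doc_id == doc.doc_id for d in entry.documents):
            raise CatalogueError(f"document {doc.doc_id!r} already attached")
        entry.documents.append(doc)
        return doc

    def add_issue(self, dataset_ref: str, text: str, *, at: str | None = None) -> DatasetIssue:
        entry = self.resolve(dataset_ref)
        issue = DatasetIssue(
            issue_id=f"{entry.dataset_id}-issue{len(entry.issues):03d}",
            text=text,
            created_at=at or utcnow_iso(),
        )
        entry.issues.append(issue)
        return issue

    def resolve_issue(self, dataset_ref: str, issue_id: str) -> DatasetIssue:
        entry = self.resolve(dataset_ref)
        for issue in entry.issues:
            if issue.issue_id == issue_id:
                issue.status = "resolved"
                return issue
        raise CatalogueError(f"unknown issue {issue_id!r}")

    # -- integrity, export, import, merge ---------------------------------

    def check_referential_integrity(self) -> list[str]:
        """Return a list of problems; empty means every reference resolves."""
        problems: list[str] = []
        for entry in self.entries():
            try:
                entry.validate()
            except CatalogueError as exc:
                problems.append(str(exc))
            lookup_ids = set(entry.lookup_map())
            for item in entry.items:
                for rule in item.validation_rules:
                    if rule.rule_kind == "lookup_membership" and rule.params["lookup_id"] not in lookup_ids:
                        problems.append(
                            f"dataset {entry.name!r} column {item.column_name!r}: "
                            f"rule references unknown lookup {rule.params['lookup_id']!r}"
                        )
                if item.lookup is not None and not item.lookup.rows:
                    problems.append(
                        f"dataset {entry.name!r} column {item.column_name!r}: empty lookup"
                    )
        return problems

    def export_document(self, dataset_ids: list[str] | None = None) -> dict:
        """Export a self-contained, re-importable portable catalogue document.

        Contains metadata only — never row-level data.  Governance tiers are
        preserved verbatim.
        """
        if dataset_ids is None:
            dataset_ids = self.dataset_ids()
        entries = [self.get(ds) for ds in dataset_ids]
        return {
            "schema_version": SCHEMA_VERSION,
            "kind": "portable_catalogue",
            "entries": [e.to_dict() for e in entries],
        }

    @classmethod
    def from_document(cls, document: dict) -> "Catalogue":
        if not isinstance(document, dict) or document.get("kind") != "portable_catalogue":
            raise CatalogueError("not a portable catalogue document")
        if document.get("schema_version") != SCHEMA_VERSION:
            raise CatalogueError(f"unsupported schema version {document.get('schema_version')!r}")
        cat = cls()
        for entry_doc in document.get("entries", []):
            entry = CatalogueEntry.from_dict(entry_doc)
            if entry.dataset_id in cat._entries:
                raise CatalogueError(f"duplicate dataset id {entry.dataset_id!r} in document")
            if cat.by_name(entry.name) is not None:
                raise CatalogueError(f"duplicate dataset name {entry.name!r} in document")
            cat._entries[entry.dataset_id] = entry
        numeric = [int(k[2:]) for k in cat._entries if re.fullmatch(r"ds\d+", k)]
        cat._counter = max(numeric, default=-1) + 1
        return cat

    def merge_contributions(self, branch_document: dict) -> MergeReport:
        """Integrate branch contributions; additive, root wins on conflict.

        New rules, descriptions for blank fields, issues, lookup codes and
        documents are added.  Conflicting edits (both sides non-blank and
        different) are flagged in the report and the root value retained.
        """
        branch = Catalogue.from_document(branch_document)
        report = MergeReport()

        def merge_description(owner: str, root_obj, branch_obj) -> None:
            if branch_obj.description == root_obj.description:
                return
            if not root_obj.description and branch_obj.description:
                root_obj.description = branch_obj.description
                report.additions.append(f"{owner}: description adopted from branch")
            elif branch_obj.description:
                report.conflicts.append(f"{owner}: description differs, root kept")

        for branch_entry in branch.entries():
            root_entry = self.by_name(branch_entry.name)
            if root_entry is None:
                report.unknown_datasets.append(branch_entry.name)
                continue
            merge_description(f"dataset {branch_entry.name}", root_entry, branch_entry)
            root_lookup_ids = set(root_entry.lookup_map())
            for lk in branch_entry.lookups:
                if lk.lookup_id not in root_lookup_ids:
                    root_entry.lookups.append(copy.deepcopy(lk))
                    report.additions.append(f"dataset {branch_entry.name}: lookup {lk.lookup_id} added")
                else:
                    root_lk = root_entry.lookup_map()[lk.lookup_id]
                    for code, desc in lk.rows.items():
                        if code not in root_lk.rows:
                            root_lk.rows[code] = desc
                            report.additions.append(
                                f"dataset {branch_entry.name}: lookup {lk.lookup_id} code {code} added"
                            )
                        elif root_lk.rows[code] != desc:
                            report.conflicts.append(
                                f"dataset {branch_entry.name}: lookup {lk.lookup_id} code {code} differs, root kept"
                            )
            for doc in branch_entry.documents:
                existing = next((d for d in root_entry.documents if d.doc_id == doc.doc_id), None)
                if existing is None:
                    root_entry.documents.append(copy.deepcopy(doc))
                    report.additions.append(f"dataset {branch_entry.name}: document {doc.doc_id} added")
                elif existing.body != doc.body or existing.title != doc.title:
                    report.conflicts.append(
                        f"dataset {branch_entry.name}: document {doc.doc_id} differs, root kept"
                    )
            root_issue_texts = {i.text for i in root_entry.issues}
            for issue in branch_entry.issues:
                if issue.text not in root_issue_texts:
                    self.add_issue(root_entry.dataset_id, issue.text, at=issue.created_at)
                    report.additions.append(f"dataset {branch_entry.name}: issue added: {issue.text!r}")
            for branch_item in branch_entry.items:
                if not root_entry.has_column(branch_item.column_name):
                    report.unknown_columns.append(f"{branch_entry.name}.{branch_item.column_name}")
                    continue
                root_item = root_entry.item(branch_item.column_name)
                owner = f"column {branch_entry.name}.{branch_item.column_name}"
                merge_description(owner, root_item, branch_item)
                if branch_item.extraction_category != root_item.extraction_category:
                    report.conflicts.append(f"{owner}: extraction category differs, root kept")
                existing_rules = [r.to_dict() for r in root_item.validation_rules]
                for rule in branch_item.validation_rules:
                    if rule.to_dict() not in existing_rules:
                        root_item.validation_rules.append(copy.deepcopy(rule))
                        report.additions.append(f"{owner}: rule {rule.rule_kind} added")
        return report
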