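"""Cohort builder: reusable filters, set-operation trees, versioned commits.

A cohort definition is an expression tree.  Leaves pair a dataset with a
filter container (AND/OR over per-row predicates); internal nodes combine
the identifier sets of their children with UNION / INTERSECT / EXCEPT.
AND is per-row, exactly as a SQL WHERE clause would evaluate it; a
per-patient conjunction across rows is expressed as an INTERSECT of two
leaves.

Committing a definition under a project freezes the evaluated member set
as a new strictly-increasing version and assigns each member a release
identifier: a pseudonym that is stable across every commit within the
project (so refreshes line up) but unrelated between projects (so extracts
cannot be linked across projects).
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass, field
from datetime import datetime

from .catalogue import parse_iso_date
from .errors import CohortError
from .store import Store

PREDICATES = ("equals", "in_set", "between", "matches_regex", "before", "after")
SET_OPS = ("UNION", "INTERSECT", "EXCEPT")


@dataclass
class FilterBlock:
    """One reusable predicate on one column of one dataset."""

    filter_id: str
    dataset_id: str
    column_name: str
    predicate: str
    params: dict = field(default_factory=dict)
    description: str = ""

    def __post_init__(self):
        if self.predicate not in PREDICATES:
            raise CohortError(f"unknown predicate {self.predicate!r}")
        if self.predicate == "matches_regex":
            try:
                re.compile(self.params.get("pattern", ""))
            except re.error as exc:
                raise CohortError(f"filter {self.filter_id}: bad regex: {exc}") from exc
        if self.predicate == "between" and float(self.params["lower"]) > float(self.params["upper"]):
            raise CohortError(f"filter {self.filter_id}: between requires lower <= upper")
        if self.predicate in ("before", "after") and parse_iso_date(self.params["date"]) is None:
            raise CohortError(f"filter {self.filter_id}: {self.predicate} requires an ISO date")

    def matches(self, value: str | None) -> bool:
        """Evaluate against one cleaned cell value; null never matches."""
        if value is None:
            return False
        if self.predicate == "equals":
            return value == str(self.params["value"])
        if self.predicate == "in_set":
            return value in {str(v) for v in self.params["values"]}
        if self.predicate == "between":
            try:
                v = float(value)
            except ValueError:
                return False
            return float(self.params["lower"]) <= v <= float(self.params["upper"])
        if self.predicate == "matches_regex":
            return re.fullmatch(self.params["pattern"], value) is not None
        if self.predicate == "before":
            return parse_iso_date(value) is not None and value < self.params["date"]
        if self.predicate == "after":
            return parse_iso_date(value) is not None and value > self.params["date"]
        raise AssertionError(self.predicate)

    def to_dict(self) -> dict:
        return {
            "filter_id": self.filter_id,
            "dataset_id": self.dataset_id,
            "column_name": self.column_name,
            "predicate": self.predicate,
            "params": dict(self.params),
            "description": self.description,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FilterBlock":
        return cls(
            filter_id=d["filter_id"],
            dataset_id=d["dataset_id"],
            column_name=d["column_name"],
            predicate=d["predicate"],
            params=dict(d.get("params", {})),
            description=d.get("description", ""),
        )


@dataclass
class FilterContainer:
    """AND/OR combination of blocks and nested containers."""

    mode: str
    children: list = field(default_factory=list)

    def __post_init__(self):
        if self.mode not in ("AND", "OR"):
            raise CohortError(f"container mode must be AND or OR, got {self.mode!r}")
        if not self.children:
            raise CohortError("container must have at least one child")

    def row_satisfies(self, row: dict) -> bool:
        results = (
            child.row_satisfies(row) if isinstance(child, FilterContainer) else child.matches(row.get(child.column_name))
            for child in self.children
        )
        return all(results) if self.mode == "AND" else any(results)

    def blocks(self) -> list[FilterBlock]:
        out = []
        for child in self.children:
            out.extend(child.blocks() if isinstance(child, FilterContainer) else [child])
        return out

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "children": [
                {"container": c.to_dict()} if isinstance(c, FilterContainer) else {"filter": c.to_dict()}
                for c in self.children
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FilterContainer":
        children = []
        for c in d.get("children", []):
            if "container" in c:
                children.append(FilterContainer.from_dict(c["container"]))
            else:
                children.append(FilterBlock.from_dict(c["filter"]))
        return cls(mode=d["mode"], children=children)


@dataclass
class DatasetLeaf:
    """A leaf of a definition tree: identifiers of rows matching a container."""

    dataset_id: str
    container: FilterContainer

    def to_dict(self) -> dict:
        return {"leaf": {"dataset_id": self.dataset_id, "container": self.container.to_dict()}}


@dataclass
class SetOpNode:
    op: str
    children: list = field(default_factory=list)

    def __post_init__(self):
        if self.op not in SET_OPS:
            raise CohortError(f"unknown set operation {self.op!r}")
        if self.op == "EXCEPT":
            if len(self.children) != 2:
                raise CohortError("EXCEPT is strictly binary")
        elif not self.children:
            raise CohortError(f"{self.op} needs at least one child")

    def to_dict(self) -> dict:
        return {"op": self.op, "children": [c.to_dict() for c in self.children]}


def _node_from_dict(d: dict):
    if "leaf" in d:
        leaf = d["leaf"]
        return DatasetLeaf(dataset_id=leaf["dataset_id"], container=FilterContainer.from_dict(leaf["container"]))
    return SetOpNode(op=d["op"], children=[_node_from_dict(c) for c in d["children"]])


@dataclass
class CohortDefinition:
    definition_id: str
    root: object  # DatasetLeaf | SetOpNode
    description: str = ""

    def to_dict(self) -> dict:
        return {
            "definition_id": self.definition_id,
            "description": self.description,
            "root": self.root.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CohortDefinition":
        return cls(
            definition_id=d["definition_id"],
            root=_node_from_dict(d["root"]),
            description=d.get("description", ""),
        )


@dataclass
class CommittedCohort:
    """A frozen, versioned identifier set with its pseudonym map."""

    cohort_id: str
    definition_id: str
    project_id: str
    version: int
    committed_at: str
    members: frozenset
    release_map: dict  # private identifier -> release identifier
    warnings: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "cohort_id": self.cohort_id,
            "definition_id": self.definition_id,
            "project_id": self.project_id,
            "version": self.version,
            "committed_at": self.committed_at,
            "members": sorted(self.members),
            "release_map": dict(self.release_map),
            "warnings": list(self.warnings),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CommittedCohort":
        return cls(
            cohort_id=d["cohort_id"],
            definition_id=d["definition_id"],
            project_id=d["project_id"],
            version=d["version"],
            committed_at=d["committed_at"],
            members=frozenset(d["members"]),
            release_map=dict(d["release_map"]),
            warnings=list(d.get("warnings", [])),
        )


# -- evaluation -----------------------------------------------------------


def evaluate_container(store: Store, dataset_ref: str, container: FilterContainer) -> set:
    """Identifiers of live rows satisfying the container, per-row semantics."""
    entry = store.catalogue.resolve(dataset_ref)
    id_col = entry.identifier_column()
    if id_col is None:
        raise CohortError(f"dataset {entry.name!r} has no identifier column")
    for block in container.blocks():
        if not entry.has_column(block.column_name):
            raise CohortError(f"filter {block.filter_id}: dataset {entry.name!r} has no column {block.column_name!r}")
    live, _ = store.dataset_state(entry.dataset_id)
    members = set()
    for rec in live.values():
        if container.row_satisfies(rec.values):
            ident = rec.values.get(id_col)
            if ident is not None:
                members.add(ident)
    return members


def evaluate_definition(store: Store, definition: CohortDefinition) -> set:
    """Set-algebra evaluation of the definition tree."""

    def walk(node) -> set:
        if isinstance(node, DatasetLeaf):
            return evaluate_container(store, node.dataset_id, node.container)
        if node.op == "UNION":
            out: set = set()
            for child in node.children:
                out |= walk(child)
            return out
        if node.op == "INTERSECT":
            sets = [walk(child) for child in node.children]
            out = sets[0]
            for s in sets[1:]:
                out &= s
            return out
        # EXCEPT, strictly binary and ordered
        return walk(node.children[0]) - walk(node.children[1])

    return walk(definition.root)


def _mint_token(project, taken: set) -> str:
    """Next 12-hex-char pseudonym from the project's seeded counter.

    Tokens containing a run of 10 or more decimal digits are skipped so a
    release identifier can never itself look like a 10-digit number to the
    CHI scanner, and collisions are skipped to keep the map injective.
    """
    while True:
        material = f"{project.seed}:{project.mint_counter}".encode()
        project.mint_counter += 1
        token = hashlib.sha256(material).hexdigest()[:12]
        if token in taken:
            continue
        if re.search(r"\d{10}", token):
            continue
        return token


def commit_cohort(
    store: Store,
    definition: CohortDefinition,
    project_id: str,
    *,
    committed_at: datetime | None = None,
) -> CommittedCohort:
    """Freeze the evaluated member set as the next version under a project."""
    project = store.get_project(project_id)
    members = evaluate_definition(store, definition)
    warnings = []
    if not members:
        warnings.append("cohort committed with zero members")

    taken = set(project.release_map.values())
    for member in sorted(members):
        if member not in project.release_map:
            token = _mint_token(project, taken)
            project.release_map[member] = token
            taken.add(token)

    key = (project_id, definition.definition_id)
    version = store.cohort_versions.get(key, 0) + 1
    store.cohort_versions[key] = version
    store.definitions[definition.definition_id] = definition
    cohort = CommittedCohort(
        cohort_id=store.next_cohort_id(),
        definition_id=definition.definition_id,
        project_id=project_id,
        version=version,
        committed_at=(committed_at or datetime.now()).isoformat(),
        members=frozenset(members),
        release_map={m: project.release_map[m] for m in members},
        warnings=warnings,
    )
    store.cohorts[cohort.cohort_id] = cohort
    return cohort


# -- rendering ------------------------------------------------------------


def _describe_container(container: FilterContainer, indent: int, lines: list[str]) -> None:
    pad = "  " * indent
    lines.append(f"{pad}{container.mode}")
    for child in container.children:
        if isinstance(child, FilterContainer):
            _describe_container(child, indent + 1, lines)
        else:
            desc = f" — {child.description}" if child.description else ""
            lines.append(
                f"{'  ' * (indent + 1)}[{child.filter_id}] {child.column_name} "
                f"{child.predicate} {child.params!r}{desc}"
            )


def describe_definition(definition: CohortDefinition, catalogue=None) -> str:
    """Deterministic human-readable rendering of the cohort logic."""
    lines = [f"Cohort definition {definition.definition_id}"]
    if definition.description:
        lines.append(f"  {definition.description}")

    def walk(node, indent: int) -> None:
        pad = "  " * indent
        if isinstance(node, DatasetLeaf):
            name = node.dataset_id
            if catalogue is not None:
                try:
                    name = f"{catalogue.get(node.dataset_id).name} ({node.dataset_id})"
                except Exception:
                    pass
            lines.append(f"{pad}dataset {name}")
            _describe_container(node.container, indent + 1, lines)
        else:
            lines.append(f"{pad}{node.op}")
            for child in node.children:
                walk(child, indent + 1)

    walk(definition.root, 1)
    return "\n".join(lines) + "\n"
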