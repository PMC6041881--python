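"""The desk-scale data store: catalogue, live/archive rows, logs, cohorts, audits.

One :class:`Store` is one data-management node.  Everything is held in plain
Python structures (rows are dicts of cleaned string values, ``None`` for
null) and persists as a single JSON document, so a store directory is
diff-able and transportable.  Row-level state per dataset:

* **live** — at most one current row per primary key, with ``valid_from``;
* **archive** — superseded rows with half-open validity ``[valid_from,
  valid_to)``, enabling as-at reconstruction.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from datetime import datetime

from .catalogue import Catalogue
from .errors import CohortError, RdmError, UnknownDatasetError


def ts_dump(t: datetime | None) -> str | None:
    return None if t is None else t.isoformat()


def ts_load(s: str | None) -> datetime | None:
    return None if s is None else datetime.fromisoformat(s)


@dataclass
class LiveRecord:
    """Current row for one primary key."""

    values: dict
    valid_from: datetime


@dataclass
class ArchiveRecord:
    """A superseded row; valid over [valid_from, valid_to)."""

    values: dict
    valid_from: datetime
    valid_to: datetime


@dataclass
class Project:
    """A research project: owns a pseudonym map and a minting seed.

    Release identifiers are never shared between projects; the same person
    receives an unrelated pseudonym under each project.
    """

    project_id: str
    seed: int
    release_map: dict = field(default_factory=dict)  # private id -> release id
    mint_counter: int = 0


class Store:
    """In-memory node state with JSON persistence."""

    def __init__(self, catalogue: Catalogue | None = None):
        self.catalogue = catalogue if catalogue is not None else Catalogue()
        self.live: dict[str, dict[tuple, LiveRecord]] = {}
        self.archive: dict[str, list[ArchiveRecord]] = {}
        self.jobs: dict[str, list] = {}  # dataset_id -> [LoadJob]
        self.last_load_time: dict[str, datetime] = {}
        self.projects: dict[str, Project] = {}
        self.definitions: dict[str, object] = {}  # definition_id -> CohortDefinition
        self.cohorts: dict[str, object] = {}  # cohort_id -> CommittedCohort
        self.cohort_versions: dict[tuple[str, str], int] = {}
        self.audits: list = []
        self.reject_threshold: float = 0.10
        self._job_counter = 0
        self._cohort_counter = 0
        self._release_counter = 0

    # -- id minting -------------------------------------------------------

    def next_job_id(self) -> str:
        self._job_counter += 1
        return f"job{self._job_counter:05d}"

    def next_cohort_id(self) -> str:
        self._cohort_counter += 1
        return f"coh{self._cohort_counter:04d}"

    def next_release_id(self) -> str:
        self._release_counter += 1
        return f"rel{self._release_counter:04d}"

    # -- dataset state ----------------------------------------------------

    def dataset_state(self, dataset_id: str) -> tuple[dict, list]:
        self.catalogue.get(dataset_id)  # raises UnknownDatasetError if unknown
        live = self.live.setdefault(dataset_id, {})
        arch = self.archive.setdefault(dataset_id, [])
        return live, arch

    def add_project(self, project_id: str, seed: int) -> Project:
        if project_id in self.projects:
            raise CohortError(f"project {project_id!r} already exists")
        project = Project(project_id=project_id, seed=int(seed))
        self.projects[project_id] = project
        return project

    def get_project(self, project_id: str) -> Project:
        try:
            return self.projects[project_id]
        except KeyError:
            raise CohortError(f"unknown project {project_id!r}") from None

    # -- persistence ------------------------------------------------------

    def to_document(self) -> dict:
        from .cohort import CohortDefinition, CommittedCohort  # local: avoid cycle
        from .load import LoadJob

        return {
            "kind": "rdm_store",
            "catalogue": self.catalogue.export_document(),
            "live": {
                ds: [
                    {"values": rec.values, "valid_from": ts_dump(rec.valid_from)}
                    for rec in recs.values()
                ]
                for ds, recs in self.live.items()
            },
            "archive": {
                ds: [
                    {
                        "values": rec.values,
                        "valid_from": ts_dump(rec.valid_from),
                        "valid_to": ts_dump(rec.valid_to),
                    }
                    for rec in recs
                ]
                for ds, recs in self.archive.items()
            },
            "jobs": {ds: [j.to_dict() for j in jobs] for ds, jobs in self.jobs.items()},
            "last_load_time": {ds: ts_dump(t) for ds, t in self.last_load_time.items()},
            "projects": {
                pid: {
                    "project_id": p.project_id,
                    "seed": p.seed,
                    "release_map": dict(p.release_map),
                    "mint_counter": p.mint_counter,
                }
                for pid, p in self.projects.items()
            },
            "definitions": {k: d.to_dict() for k, d in self.definitions.items()},
            "cohorts": {k: c.to_dict() for k, c in self.cohorts.items()},
            "cohort_versions": [
                {"project_id": p, "definition_id": d, "version": v}
                for (p, d), v in self.cohort_versions.items()
            ],
            "audits": [a.to_dict() for a in self.audits],
            "reject_threshold": self.reject_threshold,
            "counters": {
                "job": self._job_counter,
                "cohort": self._cohort_counter,
                "release": self._release_counter,
            },
        }

    @classmethod
    def from_document(cls, doc: dict) -> "Store":
        from .cohort import CohortDefinition, CommittedCohort
        from .extraction import ReleaseAudit
        from .load import LoadJob

        if doc.get("kind") != "rdm_store":
            raise RdmError("not a store document")
        store = cls(Catalogue.from_document(doc["catalogue"]))
        for ds, recs in doc.get("live", {}).items():
            entry = store.catalogue.get(ds)
            live = store.live.setdefault(ds, {})
            for rec in recs:
                key = tuple(rec["values"].get(c) for c in entry.primary_key)
                live[key] = LiveRecord(values=rec["values"], valid_from=ts_load(rec["valid_from"]))
        for ds, recs in doc.get("archive", {}).items():
            store.archive[ds] = [
                ArchiveRecord(
                    values=rec["values"],
                    valid_from=ts_load(rec["valid_from"]),
                    valid_to=ts_load(rec["valid_to"]),
                )
                for rec in recs
            ]
        for ds, jobs in doc.get("jobs", {}).items():
            store.jobs[ds] = [LoadJob.from_dict(j) for j in jobs]
        store.last_load_time = {ds: ts_load(t) for ds, t in doc.get("last_load_time", {}).items()}
        for pid, p in doc.get("projects", {}).items():
            store.projects[pid] = Project(
                project_id=p["project_id"],
                seed=p["seed"],
                release_map=dict(p.get("release_map", {})),
                mint_counter=p.get("mint_counter", 0),
            )
        store.definitions = {
            k: CohortDefinition.from_dict(d) for k, d in doc.get("definitions", {}).items()
        }
        store.cohorts = {k: CommittedCohort.from_dict(c) for k, c in doc.get("cohorts", {}).items()}
        store.cohort_versions = {
            (cv["project_id"], cv["definition_id"]): cv["version"]
            for cv in doc.get("cohort_versions", [])
        }
        store.audits = [ReleaseAudit.from_dict(a) for a in doc.get("audits", [])]
        store.reject_threshold = doc.get("reject_threshold", 0.10)
        counters = doc.get("counters", {})
        store._job_counter = counters.get("job", 0)
        store._cohort_counter = counters.get("cohort", 0)
        store._release_counter = counters.get("release", 0)
        return store

    def save(self, path: str) -> None:
        tmp = f"{path}.tmp"
        with open(tmp, "w", encoding="utf-8") as fh:
            json.dump(self.to_document(), fh, indent=1)
        os.replace(tmp, path)

    @classmethod
    def open(cls, path: str) -> "Store":
        with open(path, encoding="utf-8") as fh:
            return cls.from_document(json.load(fh))
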