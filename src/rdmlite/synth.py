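"""Seeded generator of synthetic longitudinal clinical worlds.

A *world* is a set of monthly CSV feed files for a handful of datasets
(demography, prescriptions, biochemistry, plus optional generic measure
datasets), a bootstrap portable catalogue describing them, and a ground
truth record of everything planted:

* per-column missing / wrong cells at configured rates;
* schema drift (renamed columns, dropped headers) at configured months;
* retrospective value changes re-supplied in a later feed;
* months with zero events (accrual gaps);
* checksum-valid CHI-like identifiers embedded in free-text cells.

Identifiers are 10-digit CHI-like strings whose first six digits are the
patient's date of birth (DDMMYY) and whose last digit is a valid modulus-11
check digit, so the disclosure scanner's strict mode also recognises them.
Everything is deterministic in the seed, byte for byte.  Value
distributions are deliberately simple — the worlds exercise data-management
plumbing, not biology.
"""

from __future__ import annotations

import csv
import json
import os
import random
from dataclasses import dataclass, field
from datetime import date, datetime, timedelta

from .catalogue import Catalogue, LookupRef, SupportingDocument, ValidationRuleSpec
from .errors import RdmError
from .load import run_load
from .store import Store
from . import chi as chimod

NULL_TOKEN = "NA"

_SEX_LOOKUP = {"F": "Female", "M": "Male"}
_BNF_LOOKUP = {
    "0101": "Antacids",
    "0205": "Antihypertensives",
    "0601": "Insulins",
    "0212": "Lipid-regulating drugs",
    "0403": "Antidepressants",
}
_TEST_LOOKUP = {"HBA1C": "Glycated haemoglobin", "CREAT": "Serum creatinine", "CHOL": "Total cholesterol"}
_FORENAMES = ["Alex", "Morag", "Ewan", "Isla", "Callum", "Fiona", "Rory", "Mhairi"]
_NOTE_PHRASES = [
    "routine review",
    "repeat issued",
    "dose unchanged",
    "advised follow up",
    "sample haemolysed",
    "no concerns noted",
]


@dataclass
class WorldConfig:
    """Study conditions for one synthetic world; deterministic in ``seed``."""

    seed: int = 0
    n_patients: int = 50
    n_datasets: int = 3
    months: int = 6
    start_month: str = "2016-01"
    events_per_month: int = 40
    error_rates: dict = field(
        default_factory=lambda: {"biochemistry.value": {"missing_rate": 0.05, "wrong_rate": 0.02}}
    )
    drift_plan: list = field(default_factory=list)
    rewrite_rate: float = 0.05
    gap_months: tuple = ()
    planted_chi_count: int = 0

    def __post_init__(self):
        if self.n_patients <= 0 or self.n_datasets <= 0 or self.months <= 0:
            raise RdmError("n_patients, n_datasets and months must be positive")
        for col, rates in self.error_rates.items():
            for key, rate in rates.items():
                if not 0.0 <= rate <= 1.0:
                    raise RdmError(f"error rate {col}.{key} outside [0, 1]")
        for m in self.gap_months:
            if not 0 <= m < self.months:
                raise RdmError(f"gap month {m} outside accrual period")

    def month_label(self, index: int) -> str:
        y, m = map(int, self.start_month.split("-"))
        m += index
        y += (m - 1) // 12
        m = (m - 1) % 12 + 1
        return f"{y:04d}-{m:02d}"


@dataclass
class GroundTruth:
    """Exactly what was planted, consistent with the emitted files."""

    row_counts: dict = field(default_factory=dict)  # dataset -> {month label -> rows}
    planted_missing: dict = field(default_factory=dict)  # "dataset.column" -> count
    planted_wrong: dict = field(default_factory=dict)
    rewrites: list = field(default_factory=list)
    planted_chis: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "row_counts": self.row_counts,
            "planted_missing": self.planted_missing,
            "planted_wrong": self.planted_wrong,
            "rewrites": self.rewrites,
            "planted_chis": self.planted_chis,
        }


@dataclass
class FeedFile:
    """One feed: rows ready to serialise, plus when it should be loaded."""

    dataset: str
    month_index: int
    filename: str
    load_time: datetime
    columns: list  # canonical column order of the payload
    header: list | None  # header row to write, or None for headerless
    rows: list = field(default_factory=list)  # list of dicts canonical -> str

    def write(self, out_dir: str) -> str:
        path = os.path.join(out_dir, self.filename)
        with open(path, "w", encoding="utf-8", newline="") as fh:
            writer = csv.writer(fh)
            if self.header is not None:
                writer.writerow(self.header)
            for row in self.rows:
                writer.writerow([row[c] for c in self.columns])
        return path


@dataclass
class World:
    config: WorldConfig
    out_dir: str
    catalogue_document: dict
    ground_truth: GroundTruth
    feeds: list  # FeedFile, in load order
    patients: list  # dicts with chi, sex, dob, ...

    def feed_paths(self) -> list:
        return [os.path.join(self.out_dir, f.filename) for f in self.feeds]

    def build_store(self) -> Store:
        """Fresh store with the bootstrap catalogue and all feeds loaded."""
        store = Store(Catalogue.from_document(self.catalogue_document))
        for feed in self.feeds:
            job = run_load(store, feed.dataset, os.path.join(self.out_dir, feed.filename), feed.load_time)
            if job.stage != "LIVE":
                raise RdmError(f"world feed {feed.filename} failed to load: {job.fatal_messages()}")
        return store


def _generic_name(k: int) -> str:
    return f"measure{k:03d}"


def _dataset_names(config: WorldConfig) -> list:
    names = ["demography", "prescriptions", "biochemistry"][: config.n_datasets]
    names += [_generic_name(k) for k in range(3, config.n_datasets)]
    return names


def build_bootstrap_catalogue(config: WorldConfig) -> Catalogue:
    """Catalogue entries, rules, lookups and load logic for the world."""
    cat = Catalogue()
    names = _dataset_names(config)

    def apply_drift_logic(entry):
        for step in config.drift_plan:
            if step["dataset"] != entry.name:
                continue
            if step["kind"] == "rename_column":
                entry.load_logic.header_mapping[step["alias"]] = step["column"]
            elif step["kind"] == "drop_header":
                entry.load_logic.headerless_column_order = entry.column_names()

    if "demography" in names:
        entry = cat.register_dataset(
            "demography",
            [("chi", "code"), ("sex", "code"), ("dob", "date"), ("postcode", "text"), ("forename", "text")],
            ["chi"],
            description="One row per patient: sex, date of birth, residence.",
        )
        cat.set_column_metadata(entry.dataset_id, "chi", description="patient identifier", category="Internal", role="identifier")
        cat.set_column_metadata(entry.dataset_id, "forename", description="given name", category="SpecialApprovalRequired")
        cat.set_column_metadata(entry.dataset_id, "sex", description="administrative sex")
        cat.set_column_metadata(entry.dataset_id, "dob", description="date of birth")
        cat.set_column_metadata(entry.dataset_id, "postcode", description="postcode district of residence")
        cat.add_lookup(entry.dataset_id, LookupRef("sex_codes", dict(_SEX_LOOKUP)))
        cat.attach_validation_rule(entry.dataset_id, "sex", ValidationRuleSpec("lookup_membership", {"lookup_id": "sex_codes"}))
        cat.attach_validation_rule(
            entry.dataset_id, "dob", ValidationRuleSpec("date_range", {"earliest": "1900-01-01", "latest": "2016-12-31"})
        )
        cat.add_document(
            entry.dataset_id,
            SupportingDocument("data-governance", "Data governance note", "Extracts are pseudonymised; contact the data custodian for approvals.", global_flag=True),
        )
        entry.item("sex").lookup = entry.lookup_map()["sex_codes"]
        apply_drift_logic(entry)

    if "prescriptions" in names:
        entry = cat.register_dataset(
            "prescriptions",
            [("rx_no", "text"), ("chi", "code"), ("bnf_code", "code"), ("qty", "integer"), ("event_date", "date"), ("notes", "text")],
            ["rx_no"],
            event_date_column="event_date",
            description="Dispensed prescriptions, one row per item.",
        )
        cat.set_column_metadata(entry.dataset_id, "chi", description="patient identifier", category="Internal", role="identifier")
        cat.set_column_metadata(entry.dataset_id, "bnf_code", description="BNF chapter code")
        cat.set_column_metadata(entry.dataset_id, "qty", description="quantity dispensed")
        cat.set_column_metadata(entry.dataset_id, "notes", description="dispensing free text")
        cat.add_lookup(entry.dataset_id, LookupRef("bnf_codes", dict(_BNF_LOOKUP)))
        cat.attach_validation_rule(entry.dataset_id, "bnf_code", ValidationRuleSpec("lookup_membership", {"lookup_id": "bnf_codes"}))
        cat.attach_validation_rule(entry.dataset_id, "qty", ValidationRuleSpec("bounds", {"lower": 1, "upper": 500}))
        entry.item("bnf_code").lookup = entry.lookup_map()["bnf_codes"]
        apply_drift_logic(entry)

    if "biochemistry" in names:
        entry = cat.register_dataset(
            "biochemistry",
            [("sample_no", "text"), ("chi", "code"), ("test_code", "code"), ("value", "decimal"), ("event_date", "date")],
            ["sample_no"],
            event_date_column="event_date",
            description="Laboratory results, one row per analyte measurement.",
        )
        cat.set_column_metadata(entry.dataset_id, "chi", description="patient identifier", category="Internal", role="identifier")
        cat.set_column_metadata(entry.dataset_id, "test_code", description="analyte code")
        cat.set_column_metadata(entry.dataset_id, "value", description="measured value")
        cat.add_lookup(entry.dataset_id, LookupRef("test_codes", dict(_TEST_LOOKUP)))
        cat.attach_validation_rule(entry.dataset_id, "test_code", ValidationRuleSpec("lookup_membership", {"lookup_id": "test_codes"}))
        cat.attach_validation_rule(entry.dataset_id, "value", ValidationRuleSpec("bounds", {"lower": 0, "upper": 1000}))
        entry.item("test_code").lookup = entry.lookup_map()["test_codes"]
        apply_drift_logic(entry)

    for k in range(3, config.n_datasets):
        entry = cat.register_dataset(
            _generic_name(k),
            [("rec_no", "text"), ("chi", "code"), ("value", "decimal"), ("event_date", "date")],
            ["rec_no"],
            event_date_column="event_date",
            description=f"Generic measurement feed {k}.",
        )
        cat.set_column_metadata(entry.dataset_id, "chi", description="patient identifier", category="Internal", role="identifier")
        cat.attach_validation_rule(entry.dataset_id, "value", ValidationRuleSpec("bounds", {"lower": 0, "upper": 1000}))
        apply_drift_logic(entry)
    return cat


def _make_chi(rng: random.Random, dob: date, taken: set) -> str:
    """CHI-like identifier: DDMMYY + 3 digits + valid check digit."""
    prefix = dob.strftime("%d%m%y")
    while True:
        nine = prefix + f"{rng.randrange(1000):03d}"
        candidate = chimod.make_chi(nine)
        if candidate is not None and candidate not in taken:
            taken.add(candidate)
            return candidate


def _wrong_value(semantic_type: str) -> str:
    # out-of-rule values with no digit run of length >= 10
    if semantic_type in ("integer", "decimal"):
        return "99999"
    if semantic_type == "code":
        return "ZZZZ"
    if semantic_type == "date":
        return "99-99-9999"
    return "!"


def _plant_errors(config: WorldConfig, rng: random.Random, feed: FeedFile, entry, truth: GroundTruth) -> None:
    for item in entry.items:
        key = f"{entry.name}.{item.column_name}"
        rates = config.error_rates.get(key)
        if not rates:
            continue
        mr = rates.get("missing_rate", 0.0)
        wr = rates.get("wrong_rate", 0.0)
        for row in feed.rows:
            u = rng.random()
            if u < mr:
                row[item.column_name] = NULL_TOKEN
                truth.planted_missing[key] = truth.planted_missing.get(key, 0) + 1
            elif u < mr + wr:
                row[item.column_name] = _wrong_value(item.semantic_type)
                truth.planted_wrong[key] = truth.planted_wrong.get(key, 0) + 1


def _drift_for(config: WorldConfig, dataset: str, month: int) -> dict | None:
    for step in config.drift_plan:
        if step["dataset"] == dataset and step["month"] == month:
            return step
    return None


def _feed_header(config: WorldConfig, dataset: str, month: int, columns: list) -> list | None:
    step = _drift_for(config, dataset, month)
    if step is None:
        return list(columns)
    if step["kind"] == "drop_header":
        return None
    if step["kind"] == "rename_column":
        return [step["alias"] if c == step["column"] else c for c in columns]
    raise RdmError(f"unknown drift kind {step['kind']!r}")


def generate_world(config: WorldConfig, out_dir: str) -> World:
    """Emit a complete synthetic world under ``out_dir``.

    Deterministic in ``config.seed``; the returned ground truth matches the
    emitted files exactly by construction.
    """
    rng = random.Random(config.seed)
    os.makedirs(out_dir, exist_ok=True)
    catalogue = build_bootstrap_catalogue(config)
    names = _dataset_names(config)
    truth = GroundTruth(row_counts={name: {} for name in names})

    taken: set = set()
    patients = []
    for _ in range(config.n_patients):
        dob = date(1930 + rng.randrange(70), rng.randrange(1, 13), rng.randrange(1, 29))
        patients.append(
            {
                "chi": _make_chi(rng, dob, taken),
                "sex": rng.choice(["F", "M"]),
                "dob": dob.isoformat(),
                "postcode": f"DD{rng.randrange(1, 10)} {rng.randrange(1, 10)}{rng.choice('ABCDEFGH')}{rng.choice('ABCDEFGH')}",
                "forename": rng.choice(_FORENAMES),
            }
        )

    feeds: list[FeedFile] = []
    seq = 0

    def load_time_for(month: int) -> datetime:
        nonlocal seq
        y, m = map(int, config.month_label(month).split("-"))
        seq += 1
        return datetime(y, m, 28, 12, 0, 0) + timedelta(minutes=seq)

    def new_feed(dataset: str, month: int, columns: list, filename: str | None = None) -> FeedFile:
        return FeedFile(
            dataset=dataset,
            month_index=month,
            filename=filename or f"{dataset}_m{month:02d}.csv",
            load_time=load_time_for(month),
            columns=list(columns),
            header=_feed_header(config, dataset, month, columns),
        )

    counters = {name: 0 for name in names}

    def event_rows(dataset: str, month: int, n: int) -> list:
        label = config.month_label(month)
        rows = []
        for _ in range(n):
            patient = rng.choice(patients)
            day = rng.randrange(1, 29)
            event_date = f"{label}-{day:02d}"
            counters[dataset] += 1
            if dataset == "prescriptions":
                rows.append(
                    {
                        "rx_no": f"RX{counters[dataset]:06d}",
                        "chi": patient["chi"],
                        "bnf_code": rng.choice(sorted(_BNF_LOOKUP)),
                        "qty": str(rng.randrange(1, 100)),
                        "event_date": event_date,
                        "notes": rng.choice(_NOTE_PHRASES),
                    }
                )
            elif dataset == "biochemistry":
                rows.append(
                    {
                        "sample_no": f"SM{counters[dataset]:06d}",
                        "chi": patient["chi"],
                        "test_code": rng.choice(sorted(_TEST_LOOKUP)),
                        "value": f"{min(rng.lognormvariate(3.5, 0.6), 999.0):.2f}",
                        "event_date": event_date,
                    }
                )
            else:
                rows.append(
                    {
                        "rec_no": f"RC{counters[dataset]:06d}",
                        "chi": patient["chi"],
                        "value": f"{min(rng.lognormvariate(3.0, 0.5), 999.0):.2f}",
                        "event_date": event_date,
                    }
                )
        return rows

    # demography: single full feed at month 0
    if "demography" in names:
        entry = catalogue.by_name("demography")
        feed = new_feed("demography", 0, entry.column_names())
        feed.rows = [dict(p) for p in patients]
        _plant_errors(config, rng, feed, entry, truth)
        feeds.append(feed)
        truth.row_counts["demography"][config.month_label(0)] = len(feed.rows)

    # event datasets: one feed per non-gap month
    for dataset in names:
        if dataset == "demography":
            continue
        entry = catalogue.by_name(dataset)
        for month in range(config.months):
            label = config.month_label(month)
            if month in config.gap_months:
                truth.row_counts[dataset][label] = 0
                continue
            feed = new_feed(dataset, month, entry.column_names())
            feed.rows = event_rows(dataset, month, config.events_per_month)
            _plant_errors(config, rng, feed, entry, truth)
            feeds.append(feed)
            truth.row_counts[dataset][label] = len(feed.rows)

    # retrospective rewrites: demography re-supplied in the final month
    if config.rewrite_rate > 0 and "demography" in names and config.months > 1:
        feeds.append(emit_rewrite_feed(config, catalogue, patients, rng, truth, load_time_for(config.months - 1)))

    world = World(
        config=config,
        out_dir=out_dir,
        catalogue_document=catalogue.export_document(),
        ground_truth=truth,
        feeds=sorted(feeds, key=lambda f: f.load_time),
        patients=patients,
    )
    if config.planted_chi_count:
        plant_freetext_identifiers(world, config.planted_chi_count, rng)
    _write_world(world)
    return world


def emit_rewrite_feed(config, catalogue, patients, rng, truth: GroundTruth, load_time: datetime) -> FeedFile:
    """A later demography feed re-supplying some patients with changed values.

    Emulates retrospective correction in a source system: the same primary
    keys arrive again with a different postcode, which the load engine
    records as updates and archives the superseded rows.
    """
    entry = catalogue.by_name("demography")
    month = config.months - 1
    feed = FeedFile(
        dataset="demography",
        month_index=month,
        filename=f"demography_rewrite_m{month:02d}.csv",
        load_time=load_time,
        columns=entry.column_names(),
        header=entry.column_names(),
    )
    n_rewrite = round(config.rewrite_rate * len(patients))
    for patient in rng.sample(patients, n_rewrite):
        old = patient["postcode"]
        new = old
        while new == old:
            new = f"DD{rng.randrange(1, 10)} {rng.randrange(1, 10)}{rng.choice('ABCDEFGH')}{rng.choice('ABCDEFGH')}"
        row = dict(patient)
        row["postcode"] = new
        feed.rows.append(row)
        truth.rewrites.append(
            {
                "dataset": "demography",
                "key": {"chi": patient["chi"]},
                "column": "postcode",
                "old": old,
                "new": new,
                "month": month,
            }
        )
    return feed


def plant_freetext_identifiers(world: World, count: int, rng: random.Random | None = None) -> list:
    """Embed checksum-valid CHIs in free-text cells; return their locations.

    The planted numbers are fresh (not any patient's identifier) and
    pairwise distinct, so scanner findings can be matched to plantings
    exactly.
    """
    if count == 0:
        return []
    rng = rng or random.Random(world.config.seed + 1)
    candidates = [
        (feed, i)
        for feed in world.feeds
        if feed.dataset == "prescriptions"
        for i in range(len(feed.rows))
    ]
    if count > len(candidates):
        raise RdmError(f"cannot plant {count} identifiers in {len(candidates)} free-text cells")
    taken = {p["chi"] for p in world.patients}
    locations = []
    for feed, i in rng.sample(candidates, count):
        dob = date(1930 + rng.randrange(70), rng.randrange(1, 13), rng.randrange(1, 29))
        planted = _make_chi(rng, dob, taken)
        row = feed.rows[i]
        row["notes"] = f"{row['notes']} ref {planted}"
        locations.append(
            {
                "dataset": feed.dataset,
                "file": feed.filename,
                "row_index": i,
                "column": "notes",
                "chi": planted,
            }
        )
    world.ground_truth.planted_chis.extend(locations)
    return locations


def _write_world(world: World) -> None:
    for feed in world.feeds:
        feed.write(world.out_dir)
    with open(os.path.join(world.out_dir, "ground_truth.json"), "w", encoding="utf-8") as fh:
        json.dump(world.ground_truth.to_dict(), fh, indent=1, sort_keys=True)
    with open(os.path.join(world.out_dir, "catalogue.json"), "w", encoding="utf-8") as fh:
        json.dump(world.catalogue_document, fh, indent=1, sort_keys=True)
    manifest = [
        {"dataset": f.dataset, "month": f.month_index, "file": f.filename, "load_time": f.load_time.isoformat()}
        for f in world.feeds
    ]
    with open(os.path.join(world.out_dir, "manifest.json"), "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1)
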