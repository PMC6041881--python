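# rdmlite

Desk-scale research data management for longitudinal tabular health data:
a Python library and `rdm` command-line tool that implement the integrated
data-management lifecycle used by clinical research data warehouses —
catalogue-driven loading, quality profiling, cohort building, and
reproducible pseudonymised extraction — exercised end to end on synthetic
data with known ground truth.

It is written for health-informatics engineers and research data analysts
who want the *mechanics* of a safe-haven data management platform (audit
trails, bitemporal row history, release-identifier mapping, disclosure
scanning) in a self-contained, scriptable form.

## What it does

Everything is driven by a **catalogue**: per-dataset and per-column
metadata, validation rules, lookups, load logic, and a four-tier
extraction-governance category per column (`Core`, `Supplemental`,
`SpecialApprovalRequired`, `Internal`). The catalogue exports to a
portable JSON document and researcher contributions merge back
additively, with conflicts reported and the root value retained.

Around the catalogue sit five processes:

* **Load engine** — CSV feeds pass RAW → STAGING → LIVE. RAW records the
  MD5 of the raw bytes and resolves renamed or missing headers from the
  catalogue's load logic; STAGING cleans cells (trim, null tokens, date
  parsing, code uppercasing) and rejects invalid rows with per-row logs;
  LIVE upserts on the declared primary key and archives superseded rows
  with half-open validity intervals `[valid_from, valid_to)`, so
  `reconstruct_as_at(dataset, t)` returns the table exactly as it stood at
  any past instant. Conservation holds for every load:
  `staged + rejected = raw` and `inserted + updated + unchanged = staged`.
* **Data quality** — every live cell is classified into exactly one of
  `correct` / `missing` / `wrong` against the catalogue rules, with
  monthly breakdowns, summary aggregates, and a gap-revealing quality
  timeline chart.
* **Cohort builder** — reusable filter blocks compose into AND/OR
  containers per dataset; identifier sets combine with
  UNION / INTERSECT / EXCEPT. Committing a definition under a project
  freezes a versioned member set and assigns each member a 12-hex-char
  **release identifier**: stable across refreshes within a project,
  unlinkable across projects, never derivable from the private identifier.
* **Extraction** — reconstructs each selected dataset as-at a fixed
  instant, joins to the cohort, substitutes release identifiers, then runs
  disclosure control: the governance filter (drops `Internal` and
  unapproved special-approval columns), the column blacklister (regular
  expression over column names), and the CHI scanner, which flags any
  10-digit window in any cell passing the Scottish CHI modulus-11 check

      check = 11 − (Σᵢ wᵢ·dᵢ mod 11),  w = (10, 9, …, 2),  11 → 0,
      10 → no valid check digit

  A finding vetoes the whole release (fail closed); the audit records the
  crash messages and no bundle is written. Successful releases are
  directories with per-dataset CSVs, lookups, global documents, an
  extract-time quality report, a metadata document, a tailored branch
  catalogue, and a digest manifest — byte-identical when re-run with the
  same configuration and as-at time.
* **Synthetic worlds** — a seeded generator emits monthly feeds
  (demography, prescriptions, biochemistry, optional extras) with planted
  missingness and errors, schema drift, retrospective value rewrites,
  accrual gaps and embedded checksum-valid CHIs, plus the exact ground
  truth, so every pipeline above is testable without any real data.

## Worked example

```
$ rdm synth generate world --seed 5 --months 3 --patients 20
world written to world: 8 feeds, 20 patients
```

Load the feeds (the test world's bootstrap catalogue already knows the
schemas, rules and lookups), then ask for a load history and a quality
report:

```
$ rdm load history biochemistry
[
 {
  "job_id": "job00003",
  "stage": "LIVE",
  "file_digest": "7c50a14b37dafb6c6b637923aff3c0db",
  "raw": 40, "staged": 40, "rejected": 0,
  "inserted": 40, "updated": 0, "unchanged": 0,
  "load_time": "2016-01-28T12:05:00", "fatal": []
 },
 ...
]

$ rdm dq report biochemistry        # value column, 120 live rows
 "row_count": 120,
 "value": {"correct": 115, "missing": 3, "wrong": 2}

$ rdm dq aggregate demography --by sex
 "cells": {"F": 7, "M": 13}, "total": 20
```

The three missing and two wrong cells are exactly the ones the generator
planted (5% missing rate, 2% wrong rate on the lab value column over 120
rows): the quality process recovers planted defects count-for-count. An
extraction against a committed cohort then produces a release bundle, or
exits with code 3 if any disclosure component vetoes — for example when a
checksum-valid CHI number is hiding in dispensing free text.

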