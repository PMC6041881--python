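# Methods

This note documents the model of data management that rdmlite implements,
the parameters that matter, the synthetic-data conditions under which it
is tested, and the design choices made where the design was genuinely
open.

## The lifecycle model

rdmlite treats a research data repository as a *catalogue* plus five
processes (load, catalogue management, quality, summary, extraction) that
all consult the catalogue and nothing else for schema, rules and
governance. The key modelling commitments:

**Cell model.** After cleaning, every cell is a string or null. Semantic
types (`integer`, `decimal`, `date`, `code`) are interpretations applied
at validation and filtering time, not storage types. Dates normalise to
ISO 8601 during staging; unparseable dates are kept verbatim and
classified `wrong` by the quality process rather than rejected, because a
bad date in a non-key column should not cost the row.

**Bitemporal history.** The live table holds at most one row per primary
key. An update moves the superseded row to the archive with validity
`[valid_from, valid_to)` (half-open, so an as-at query at exactly the
load time sees the new row). As-at reconstruction is then: live rows with
`valid_from ≤ t` plus archive rows whose interval covers `t`. Loads per
dataset must carry strictly increasing load times (a monotonic load
clock); back-dated loads are rejected because they would make past
reconstructions ambiguous. Source feeds never delete implicitly — an
explicit tombstone operation archives a row without replacement.

**Upsert accounting.** A staged row whose payload equals the live row is
counted `unchanged`, not `updated`; only genuine value changes archive a
row. This makes reloading a file a no-op (idempotence) and makes the
conservation identity `inserted + updated + unchanged = staged` hold
exactly, alongside `staged + rejected = raw`.

**Quality classification.** Each cell is `missing` (null, or violating a
rule whose severity is `missing`), `wrong` (violating a `wrong`-severity
rule, or failing its semantic type), else `correct` — a partition, so
counts always sum to the row count per column and per month. The eight
classical quality dimensions map as: accuracy → rule conformance,
completeness → null rate, consistency → lookup membership, timeliness →
days since last successful load, uniqueness → duplicate primary keys
(zero by construction of the live table, but re-counted rather than
assumed). Accessibility and access security are organisational properties
recorded only as report metadata flags; relevancy has no operational
definition from data alone and is out of computed scope.

**Cohort semantics.** AND containers are per-row conjunctions, exactly as
the SQL `WHERE` clause a query builder would emit; a per-patient
conjunction across rows is expressed as an INTERSECT of two leaves.
EXCEPT is strictly binary and ordered. Filters never match null cells.

**Pseudonymisation.** Release identifiers are 12 lowercase hex characters
minted from SHA-256 over `(project seed, counter)`. The map is persisted
per project and only ever grows, so identifier → release-ID is a stable
injective function across all commits and refreshes of a project, while
two projects' maps are unrelated (different seeds). Tokens are
non-derivable from the private identifier (the identifier never enters
the hash). Two hardening details: a candidate token containing a run of
ten or more decimal digits is skipped, so a release identifier can never
itself trip the CHI scanner; and colliding candidates are skipped to keep
the map injective. Release-identifier stability is chosen per-project
(not per-release) because refresh reproducibility requires the same
person to carry the same pseudonym in every re-release.

**Disclosure control.** The extraction pipeline is fail-closed: the
blacklister and CHI scanner veto the entire release rather than redact,
because a blocked release is recoverable and a leaked identifier is not.
An explicit `redact` mode (masking findings with `XXXXXXXXXX`) exists but
is never the default. The scanner examines every 10-digit window within
every maximal digit run of length ≥ 10 in every cell — the conservative
superset of delimiter conventions. The modulus-11 check uses weights
10…2 over the first nine digits with `check = 11 − (sum mod 11)`, 11 → 0,
and remainder 1 (check value 10) meaning no valid check digit exists.
Date plausibility of the DDMMYY prefix is *not* required for a finding
(checksum only); a strict mode adds it. The pipeline's own `release_id`
column is exempt from the blacklister — it is the pseudonym the pipeline
itself just inserted — but not from the scanner.

**Refresh reproducibility.** Extraction always reads through the as-at
reconstruction (a "live" extraction is as-at the extraction instant), and
output rows are sorted by release identifier then primary key with fixed
column order, so re-running a configuration with the same as-at time and
cohort version is byte-identical, and a refresh that only adds rows keeps
headers and column order stable.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `Store.reject_threshold` | 0.10 | fraction of rejected rows above which a staging run fails fatally |
| null tokens | `""`, `"NULL"`, `"NA"` | feed values cleaned to null |
| date formats | ISO, `DD/MM/YYYY` | tried in order during staging |
| aggregate cardinality limit | 1000 | distinct values above which a summary aggregate is refused |
| release token length | 12 hex chars | pseudonym space (≈ 2.8 × 10¹⁴) |
| `WorldConfig.n_patients` | 50 | synthetic patients |
| `WorldConfig.months` | 6 | accrual period |
| `WorldConfig.events_per_month` | 40 | event rows per dataset per month |
| `WorldConfig.error_rates` | 5% missing, 2% wrong on the lab value | planted defect rates |
| `WorldConfig.rewrite_rate` | 0.05 | fraction of patients re-supplied with changed values in a later feed |

## What the synthetic worlds do and do not show

The generator emulates the *data-management* phenomena of continuously
accruing clinical feeds: renamed and dropped headers, null tokens,
out-of-range and out-of-vocabulary values at known rates, months with no
events, retrospective corrections re-supplying old primary keys, and
checksum-valid identifiers leaking into free text. Identifiers are
CHI-like (DDMMYY birth-date prefix consistent with the patient's
generated date of birth, valid check digit). Value distributions are
deliberately simple — categorical sex, uniform event dates within a
month, clamped log-normal lab values — because the artifact tests
plumbing, not biology. Passing tests therefore demonstrate correctness of
loading, history, classification, set algebra and disclosure control
under realistic *structural* conditions; they say nothing about
statistical fidelity to any real population, clinically plausible
trajectories, or fuzzy identifier matching (identifiers are exact-match
by assumption).

Problem sizes in the acceptance script are desk-scale by design: 100
datasets × a handful of rows for the wide-linkage run, 200 catalogue
registrations, 50 randomised load sequences, 200 random cohort trees,
four randomised quality worlds. These sizes exercise every code path
while keeping the whole run under a few seconds.

## Numerical and degenerate-input choices

* Bounds and between-filters compare as floats; unparseable numerics
  violate bounds rules (wrong) and never match numeric filters.
* Dates compare as ISO strings (lexicographic = chronological).
* In-batch duplicate primary keys: the first occurrence wins, later ones
  are rejected and logged — deterministic and order-preserving.
* Empty feed files ingest as RAW jobs with zero rows and a warning, not
  errors; empty cohorts commit with a warning (researchers may want a
  placeholder cohort before data accrues).
* Month bucketing uses the catalogue's event-date column; rows with null
  or invalid event dates fall into an `undated` bucket, which the
  timeline reports separately rather than plotting.
* The quality timeline's month axis is the contiguous range from first to
  last observed month, so interior accrual gaps appear as explicit zero
  points.
* Catalogue merge is additive with root-wins conflict reporting: blank
  root descriptions adopt branch text, differing non-blank descriptions
  are flagged and the root kept; nothing in the root is ever silently
  overwritten. Merging a catalogue's own export back into it is a no-op.

## Storage

A node persists as a single JSON document (catalogue, live and archive
rows, load logs, projects and release maps, cohorts, audits). JSON was
chosen over an embedded database file because a text store is diff-able,
greppable and trivially transportable at desk scale; the contract that
matters — tabular rows, per-load atomicity, single writer — is preserved,
and the document format is versioned for migration. The CLI documents a
single-writer contract; concurrent multi-user access is out of scope.

## Known limitations

* No remote-source fetching, DBMS push-down, or query optimisation; all
  evaluation is in-process row scans, linear in table size.
* Disclosure control is the catalogue tiers plus the two blanket
  components; no statistical disclosure control (k-anonymity etc.).
* The release metadata document is Markdown, not a word-processor file;
  content, not format, is the contract.
* Raw feed files are digested and logged but not copied into an archive
  directory; retention of source files is the caller's concern.
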