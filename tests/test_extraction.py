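import json
import os
from datetime import datetime

import pandas as pd
import pytest

from oracles import md5_hex
from rdmlite import (
    Catalogue,
    CohortDefinition,
    DatasetLeaf,
    DatasetSelection,
    ExtractionConfiguration,
    ExtractionError,
    ExtractionVetoed,
    FilterBlock,
    FilterContainer,
    column_blacklister,
    commit_cohort,
    governance_filter,
    reconstruct_as_at,
    run_extraction,
)
from rdmlite.chi import scan_for_chi
from rdmlite.extraction import generate_branch_catalogue, generate_release_document
from rdmlite.synth import WorldConfig, generate_world


def all_patient_cohort(store, world, project="proj1", seed=101):
    if project not in store.projects:
        store.add_project(project, seed)
    demo = store.catalogue.by_name("demography")
    chis = sorted(p["chi"] for p in world.patients)
    definition = CohortDefinition(
        "def-all",
        DatasetLeaf(demo.dataset_id, FilterContainer("AND", [FilterBlock("f-all", demo.dataset_id, "chi", "in_set", {"values": chis}, "all patients")])),
        "every generated patient",
    )
    return commit_cohort(store, definition, project, committed_at=datetime(2016, 12, 1))


def full_config(store, cohort, as_at, config_id="cfg1", **kwargs):
    demo = store.catalogue.by_name("demography")
    return ExtractionConfiguration(
        config_id,
        cohort.project_id,
        cohort.cohort_id,
        selections=[DatasetSelection(e.dataset_id) for e in store.catalogue.entries()],
        special_approval_columns={demo.dataset_id: ["forename"]} if demo else {},
        as_at=as_at,
        **kwargs,
    )


@pytest.fixture(scope="module")
def clean_world(tmp_path_factory):
    out = tmp_path_factory.mktemp("clean_world")
    return generate_world(WorldConfig(seed=21, rewrite_rate=0.1), str(out))


@pytest.fixture
def clean_setup(clean_world, tmp_path):
    store = clean_world.build_store()
    cohort = all_patient_cohort(store, clean_world)
    return store, cohort, str(tmp_path)


AS_AT = datetime(2016, 12, 1)


class TestGovernance:
    def test_internal_identifier_never_in_output(self, clean_setup):
        store, cohort, out = clean_setup
        bundle, _ = run_extraction(store, full_config(store, cohort, AS_AT), out)
        for name, frame in bundle.frames.items():
            assert "chi" not in frame.columns
            assert "release_id" in frame.columns

    def test_approved_special_column_retained(self, clean_setup):
        store, cohort, out = clean_setup
        bundle, _ = run_extraction(store, full_config(store, cohort, AS_AT), out)
        assert "forename" in bundle.frames["demography"].columns

    def test_unapproved_special_column_removed_and_logged(self, clean_setup):
        store, cohort, out = clean_setup
        config = full_config(store, cohort, AS_AT)
        config.special_approval_columns = {}
        bundle, audit = run_extraction(store, config, out)
        assert "forename" not in bundle.frames["demography"].columns
        assert "forename" in audit.governance_removals.get("demography", [])

    def test_governance_filter_unit(self, clean_setup):
        store, _, _ = clean_setup
        entry = store.catalogue.by_name("demography")
        table = pd.DataFrame({"chi": ["x"], "sex": ["F"], "forename": ["Ann"]}, dtype=object)
        filtered, removed = governance_filter(table, entry, approved=set())
        assert list(filtered.columns) == ["sex"]
        assert sorted(removed) == ["chi", "forename"]

    def test_selecting_internal_column_rejected_at_config(self, clean_setup):
        # governance validation needs the catalogue, so it happens at run time
        store, cohort, _ = clean_setup
        demo = store.catalogue.by_name("demography")
        config = ExtractionConfiguration(
            "bad", cohort.project_id, cohort.cohort_id,
            selections=[DatasetSelection(demo.dataset_id, columns=["chi", "sex"])],
            as_at=AS_AT,
        )
        with pytest.raises(ExtractionError, match="Internal"):
            run_extraction(store, config, "unused")


class TestBlacklister:
    def test_matching_column_vetoes_with_name(self):
        table = pd.DataFrame({"PatientId": ["1"], "sex": ["F"]}, dtype=object)
        with pytest.raises(ExtractionVetoed, match="PatientId"):
            column_blacklister(table, r"id|address|identifier")

    def test_clean_table_passes_unchanged(self):
        table = pd.DataFrame({"sex": ["F"], "dob": ["2000-01-01"]}, dtype=object)
        assert column_blacklister(table, r"id|address|identifier") is table

    def test_empty_pattern_rejected(self):
        table = pd.DataFrame({"sex": ["F"]}, dtype=object)
        with pytest.raises(ExtractionError):
            column_blacklister(table, "")

    def test_release_id_column_exempt(self):
        table = pd.DataFrame({"release_id": ["ab12"], "sex": ["F"]}, dtype=object)
        assert column_blacklister(table, r"id") is table

    def test_end_to_end_veto_recorded_in_audit(self, clean_setup):
        store, cohort, out = clean_setup
        config = full_config(store, cohort, AS_AT, blacklist_pattern=r"postcode")
        with pytest.raises(ExtractionVetoed) as excinfo:
            run_extraction(store, config, out)
        audit = excinfo.value.audit
        assert audit.crash_messages
        assert not audit.succeeded
        assert not os.path.exists(os.path.join(out, audit.release_id))


class TestChiVeto:
    def test_planted_chis_veto_and_findings_match(self, tmp_path):
        world = generate_world(WorldConfig(seed=22, planted_chi_count=5), str(tmp_path / "w"))
        store = world.build_store()
        cohort = all_patient_cohort(store, world)
        config = full_config(store, cohort, AS_AT)
        with pytest.raises(ExtractionVetoed) as excinfo:
            run_extraction(store, config, str(tmp_path / "rel"))
        found = sorted(f.matched for f in excinfo.value.findings)
        planted = sorted(x["chi"] for x in world.ground_truth.planted_chis)
        assert found == planted

    def test_redact_mode_masks_instead_of_vetoing(self, tmp_path):
        world = generate_world(WorldConfig(seed=23, planted_chi_count=3), str(tmp_path / "w"))
        store = world.build_store()
        cohort = all_patient_cohort(store, world)
        config = full_config(store, cohort, AS_AT, redact=True)
        bundle, audit = run_extraction(store, config, str(tmp_path / "rel"))
        notes = " ".join(v for v in bundle.frames["prescriptions"]["notes"] if v)
        for planted in world.ground_truth.planted_chis:
            assert planted["chi"] not in notes
        assert "XXXXXXXXXX" in notes

    def test_clean_world_bundle_rescans_clean(self, clean_setup):
        """Disclosure safety: re-scanning every emitted data file finds nothing."""
        store, cohort, out = clean_setup
        bundle, _ = run_extraction(store, full_config(store, cohort, AS_AT), out)
        for name, rel in bundle.data_files.items():
            frame = pd.read_csv(bundle.file_path(rel), dtype=str, keep_default_na=False)
            assert scan_for_chi(frame, name) == []


class TestBundle:
    def test_one_file_per_dataset_with_manifest_digests(self, clean_setup):
        store, cohort, out = clean_setup
        bundle, _ = run_extraction(store, full_config(store, cohort, AS_AT), out)
        assert set(bundle.data_files) == {e.name for e in store.catalogue.entries()}
        for rel, digests in bundle.manifest["files"].items():
            with open(bundle.file_path(rel), "rb") as fh:
                data = fh.read()
            assert digests["md5"] == md5_hex(data)

    def test_lookups_and_global_documents_included(self, clean_setup):
        store, cohort, out = clean_setup
        bundle, _ = run_extraction(store, full_config(store, cohort, AS_AT), out)
        assert os.path.exists(bundle.file_path("lookups/bnf_codes.csv"))
        assert os.path.exists(bundle.file_path("docs/data-governance.md"))

    def test_cohort_restriction_matches_brute_force(self, clean_world, tmp_path):
        store = clean_world.build_store()
        store.add_project("proj1", 101)
        demo = store.catalogue.by_name("demography")
        members = sorted(p["chi"] for p in clean_world.patients)[:7]
        definition = CohortDefinition(
            "def7",
            DatasetLeaf(demo.dataset_id, FilterContainer("AND", [FilterBlock("f", demo.dataset_id, "chi", "in_set", {"values": members})])),
        )
        cohort = commit_cohort(store, definition, "proj1")
        config = full_config(store, cohort, AS_AT)
        bundle, _ = run_extraction(store, config, str(tmp_path))
        for entry in store.catalogue.entries():
            as_at_table = reconstruct_as_at(store, entry.dataset_id, AS_AT)
            expected = sum(1 for _, row in as_at_table.iterrows() if row["chi"] in members)
            assert len(bundle.frames[entry.name]) == expected

    def test_extract_audit_rows_created(self, clean_setup):
        store, cohort, out = clean_setup
        bundle, audit = run_extraction(store, full_config(store, cohort, AS_AT), out)
        for name, frame in bundle.frames.items():
            assert audit.rows_created[name] == len(frame)
        assert audit.succeeded


class TestRefreshReproducibility:
    def test_same_as_at_is_byte_identical(self, clean_world, tmp_path):
        store = clean_world.build_store()
        cohort = all_patient_cohort(store, clean_world)
        config = full_config(store, cohort, AS_AT)
        b1, _ = run_extraction(store, config, str(tmp_path / "r1"))
        b2, _ = run_extraction(store, config, str(tmp_path / "r2"))
        for rel in b1.data_files.values():
            with open(b1.file_path(rel), "rb") as f1, open(b2.file_path(rel), "rb") as f2:
                assert f1.read() == f2.read()

    def test_as_at_first_release_unaffected_by_later_rewrites(self, clean_world, tmp_path):
        from rdmlite.load import run_load

        store = Catalogue.from_document(clean_world.catalogue_document)
        from rdmlite import Store

        store = Store(store)
        rewrite_feeds = [f for f in clean_world.feeds if "rewrite" in f.filename]
        assert rewrite_feeds, "world must contain a rewrite feed"
        first_feeds = [f for f in clean_world.feeds if "rewrite" not in f.filename]
        for feed in first_feeds:
            run_load(store, feed.dataset, os.path.join(clean_world.out_dir, feed.filename), feed.load_time)
        cohort = all_patient_cohort(store, clean_world)
        t1 = max(f.load_time for f in first_feeds)
        config = full_config(store, cohort, t1)
        b1, _ = run_extraction(store, config, str(tmp_path / "r1"))
        for feed in rewrite_feeds:
            run_load(store, feed.dataset, os.path.join(clean_world.out_dir, feed.filename), feed.load_time)
        b2, _ = run_extraction(store, config, str(tmp_path / "r2"))
        for rel in b1.data_files.values():
            with open(b1.file_path(rel), "rb") as f1, open(b2.file_path(rel), "rb") as f2:
                assert f1.read() == f2.read()
        # live extraction now differs exactly at the rewritten keys
        live_config = full_config(store, cohort, max(f.load_time for f in rewrite_feeds), config_id="cfg-live")
        b3, _ = run_extraction(store, live_config, str(tmp_path / "r3"))
        demo1 = b1.frames["demography"].set_index("release_id")
        demo3 = b3.frames["demography"].set_index("release_id")
        changed = {
            rid for rid in demo3.index
            if demo1.loc[rid, "postcode"] != demo3.loc[rid, "postcode"]
        }
        expected = {cohort.release_map[r["key"]["chi"]] for r in clean_world.ground_truth.rewrites}
        assert changed == expected


class TestDocuments:
    def test_release_document_covers_exactly_extracted_fields(self, clean_setup):
        store, cohort, out = clean_setup
        demo = store.catalogue.by_name("demography")
        config = ExtractionConfiguration(
            "cfg-two", cohort.project_id, cohort.cohort_id,
            selections=[DatasetSelection(demo.dataset_id, columns=["sex", "dob"])],
            as_at=AS_AT,
        )
        bundle, _ = run_extraction(store, config, out)
        doc = generate_release_document(store, config, cohort, bundle.frames)
        assert "| sex |" in doc and "| dob |" in doc
        assert "| postcode |" not in doc and "| forename |" not in doc

    def test_release_document_deterministic(self, clean_setup):
        store, cohort, out = clean_setup
        config = full_config(store, cohort, AS_AT)
        bundle, _ = run_extraction(store, config, out)
        assert generate_release_document(store, config, cohort, bundle.frames) == generate_release_document(store, config, cohort, bundle.frames)

    def test_cohort_logic_section_matches_describe(self, clean_setup):
        from rdmlite import describe_definition

        store, cohort, out = clean_setup
        config = full_config(store, cohort, AS_AT)
        bundle, _ = run_extraction(store, config, out)
        doc = generate_release_document(store, config, cohort, bundle.frames)
        rendering = describe_definition(store.definitions[cohort.definition_id], store.catalogue)
        assert rendering.rstrip("\n") in doc


class TestBranchCatalogue:
    def test_restricted_and_importable(self, clean_setup):
        store, cohort, _ = clean_setup
        config = full_config(store, cohort, AS_AT)
        doc = generate_branch_catalogue(store, config)
        branch = Catalogue.from_document(doc)
        assert len(branch) == len(store.catalogue)
        for entry in branch.entries():
            assert all(item.extraction_category != "Internal" for item in entry.items)
            assert entry.identifier_column() is None

    def test_round_trips(self, clean_setup):
        store, cohort, _ = clean_setup
        doc = generate_branch_catalogue(store, full_config(store, cohort, AS_AT))
        assert Catalogue.from_document(doc).export_document() == doc

    def test_single_dataset_extract_single_entry(self, clean_setup):
        store, cohort, _ = clean_setup
        demo = store.catalogue.by_name("demography")
        config = ExtractionConfiguration(
            "cfg-one", cohort.project_id, cohort.cohort_id,
            selections=[DatasetSelection(demo.dataset_id, columns=["sex", "dob"])],
            as_at=AS_AT,
        )
        doc = generate_branch_catalogue(store, config)
        assert len(doc["entries"]) == 1
        assert {i["column_name"] for i in doc["entries"][0]["items"]} == {"sex", "dob"}
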