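import random
from datetime import datetime

import pytest

from conftest import write_csv, t
from rdmlite import (
    Catalogue,
    CohortDefinition,
    CohortError,
    DatasetLeaf,
    FilterBlock,
    FilterContainer,
    SetOpNode,
    Store,
    commit_cohort,
    describe_definition,
    evaluate_container,
    evaluate_definition,
    run_load,
)


def toy_store(tmp_path, n_datasets=3, rows_per_ds=12, seed=0):
    """Small datasets sharing a pid identifier, with x (integer) and g (code)."""
    rng = random.Random(seed)
    cat = Catalogue()
    store = Store(cat)
    data = {}
    for k in range(n_datasets):
        name = f"toy{k}"
        entry = cat.register_dataset(
            name, [("row", "text"), ("pid", "code"), ("x", "integer"), ("g", "code")], ["row"]
        )
        cat.set_column_metadata(name, "pid", category="Internal", role="identifier")
        rows = [
            [f"r{k}_{i}", f"P{rng.randint(0, 7)}", str(rng.randint(0, 99)), rng.choice(["A", "B", "C"])]
            for i in range(rows_per_ds)
        ]
        data[entry.dataset_id] = rows
        path = write_csv(tmp_path / f"{name}.csv", ["row", "pid", "x", "g"], rows)
        run_load(store, name, path, t(k + 1))
    return store, data


def brute_force_container(rows, container):
    """Row-scan oracle with independently coded predicate semantics."""

    def block_matches(block, row):
        value = row[{"row": 0, "pid": 1, "x": 2, "g": 3}[block.column_name]]
        p = block.params
        if block.predicate == "equals":
            return value == str(p["value"])
        if block.predicate == "in_set":
            return value in [str(v) for v in p["values"]]
        if block.predicate == "between":
            return float(p["lower"]) <= float(value) <= float(p["upper"])
        if block.predicate == "matches_regex":
            import re

            return re.fullmatch(p["pattern"], value) is not None
        raise AssertionError(block.predicate)

    def satisfies(node, row):
        if isinstance(node, FilterContainer):
            results = [satisfies(c, row) for c in node.children]
            return all(results) if node.mode == "AND" else any(results)
        return block_matches(node, row)

    return {row[1] for row in rows if satisfies(container, row)}


class TestContainers:
    def test_tautology_matches_everyone(self, tmp_path):
        store, data = toy_store(tmp_path, n_datasets=1)
        ds = store.catalogue.resolve("toy0").dataset_id
        container = FilterContainer(
            "OR",
            [
                FilterBlock("f1", ds, "g", "in_set", {"values": ["A", "B", "C"]}),
            ],
        )
        expected = {row[1] for row in data[ds]}
        assert evaluate_container(store, ds, container) == expected

    def test_and_matches_row_scan_oracle(self, tmp_path):
        store, data = toy_store(tmp_path, n_datasets=1)
        ds = store.catalogue.resolve("toy0").dataset_id
        container = FilterContainer(
            "AND",
            [
                FilterBlock("f1", ds, "x", "between", {"lower": 20, "upper": 70}),
                FilterBlock("f2", ds, "g", "equals", {"value": "A"}),
            ],
        )
        assert evaluate_container(store, ds, container) == brute_force_container(data[ds], container)

    def test_empty_dataset_empty_set(self, demography_store):
        store, entry = demography_store
        container = FilterContainer("AND", [FilterBlock("f", entry.dataset_id, "sex", "equals", {"value": "F"})])
        assert evaluate_container(store, entry.dataset_id, container) == set()

    def test_unknown_column_rejected(self, tmp_path):
        store, _ = toy_store(tmp_path, n_datasets=1)
        ds = store.catalogue.resolve("toy0").dataset_id
        container = FilterContainer("AND", [FilterBlock("f", ds, "ghost", "equals", {"value": "1"})])
        with pytest.raises(CohortError):
            evaluate_container(store, ds, container)

    def test_null_cells_never_match(self, tmp_path):
        store, _ = toy_store(tmp_path, n_datasets=1)
        ds = store.catalogue.resolve("toy0").dataset_id
        container = FilterContainer("AND", [FilterBlock("f", ds, "g", "matches_regex", {"pattern": ".*"})])
        live = store.live[ds]
        key = next(iter(live))
        live[key].values["g"] = None
        members_with_null = evaluate_container(store, ds, container)
        assert live[key].values["pid"] not in members_with_null or any(
            rec.values["pid"] == live[key].values["pid"] and rec.values["g"] is not None
            for rec in live.values()
        )


class TestDefinitions:
    def test_union_and_except(self, tmp_path):
        store, data = toy_store(tmp_path)
        ids = store.catalogue.dataset_ids()

        def leaf(ds, g):
            return DatasetLeaf(ds, FilterContainer("AND", [FilterBlock(f"f{g}", ds, "g", "equals", {"value": g})]))

        union = CohortDefinition("d1", SetOpNode("UNION", [leaf(ids[0], "A"), leaf(ids[1], "B")]))
        a = brute_force_container(data[ids[0]], FilterContainer("AND", [FilterBlock("x", ids[0], "g", "equals", {"value": "A"})]))
        b = brute_force_container(data[ids[1]], FilterContainer("AND", [FilterBlock("x", ids[1], "g", "equals", {"value": "B"})]))
        assert evaluate_definition(store, union) == a | b
        diff = CohortDefinition("d2", SetOpNode("EXCEPT", [leaf(ids[0], "A"), leaf(ids[1], "B")]))
        assert evaluate_definition(store, diff) == a - b

    def test_except_must_be_binary(self):
        with pytest.raises(CohortError):
            SetOpNode("EXCEPT", [])

    def test_random_trees_match_brute_force(self, tmp_path):
        """Randomised filter/set-operation trees agree with set-algebra oracle."""
        store, data = toy_store(tmp_path, seed=5)
        ids = store.catalogue.dataset_ids()
        rng = random.Random(99)

        def random_block(ds, depth_tag):
            kind = rng.choice(["equals", "between", "in_set"])
            fid = f"f{depth_tag}_{rng.randint(0, 9999)}"
            if kind == "equals":
                return FilterBlock(fid, ds, "g", "equals", {"value": rng.choice(["A", "B", "C"])})
            if kind == "between":
                lo = rng.randint(0, 60)
                return FilterBlock(fid, ds, "x", "between", {"lower": lo, "upper": lo + rng.randint(0, 40)})
            return FilterBlock(fid, ds, "pid", "in_set", {"values": [f"P{rng.randint(0, 7)}" for _ in range(3)]})

        def random_container(ds, depth):
            mode = rng.choice(["AND", "OR"])
            children = []
            for i in range(rng.randint(1, 3)):
                if depth > 0 and rng.random() < 0.3:
                    children.append(random_container(ds, depth - 1))
                else:
                    children.append(random_block(ds, depth))
            return FilterContainer(mode, children)

        def random_node(depth):
            if depth == 0 or rng.random() < 0.4:
                ds = rng.choice(ids)
                return DatasetLeaf(ds, random_container(ds, 1))
            op = rng.choice(["UNION", "INTERSECT", "EXCEPT"])
            n = 2 if op == "EXCEPT" else rng.randint(1, 3)
            return SetOpNode(op, [random_node(depth - 1) for _ in range(n)])

        def oracle(node):
            if isinstance(node, DatasetLeaf):
                return brute_force_container(data[node.dataset_id], node.container)
            sets = [oracle(c) for c in node.children]
            if node.op == "UNION":
                out = set()
                for s in sets:
                    out |= s
                return out
            if node.op == "INTERSECT":
                out = sets[0]
                for s in sets[1:]:
                    out &= s
                return out
            return sets[0] - sets[1]

        for i in range(100):
            definition = CohortDefinition(f"def{i}", random_node(3))
            assert evaluate_definition(store, definition) == oracle(definition.root), i


class TestCommits:
    def _definition(self, store, values):
        ds = store.catalogue.resolve("toy0").dataset_id
        return CohortDefinition(
            "defX",
            DatasetLeaf(ds, FilterContainer("AND", [FilterBlock("f", ds, "pid", "in_set", {"values": values})])),
        )

    def test_first_commit_mints_fresh_ids(self, tmp_path):
        store, data = toy_store(tmp_path, n_datasets=1)
        store.add_project("proj1", seed=101)
        pids = sorted({r[1] for r in data[store.catalogue.resolve("toy0").dataset_id]})[:2]
        cohort = commit_cohort(store, self._definition(store, pids), "proj1")
        assert cohort.version == 1
        assert set(cohort.release_map) == set(pids)
        assert len(set(cohort.release_map.values())) == 2

    def test_release_map_stable_across_commits(self, tmp_path):
        store, data = toy_store(tmp_path, n_datasets=1)
        store.add_project("proj1", seed=101)
        pids = sorted({r[1] for r in data[store.catalogue.resolve("toy0").dataset_id]})
        first = commit_cohort(store, self._definition(store, pids[:2]), "proj1")
        second = commit_cohort(store, self._definition(store, pids[:3]), "proj1")
        assert second.version == 2
        for pid in pids[:2]:
            assert second.release_map[pid] == first.release_map[pid]
        assert second.release_map[pids[2]] not in set(first.release_map.values())

    def test_release_map_injective_over_many_commits(self, tmp_path):
        store, data = toy_store(tmp_path, n_datasets=1)
        store.add_project("proj1", seed=101)
        pids = sorted({r[1] for r in data[store.catalogue.resolve("toy0").dataset_id]})
        for i in range(1, len(pids) + 1):
            commit_cohort(store, self._definition(store, pids[:i]), "proj1")
        final = store.projects["proj1"].release_map
        assert len(set(final.values())) == len(final)

    def test_cross_project_unlinkability(self, tmp_path):
        store, data = toy_store(tmp_path, n_datasets=1)
        store.add_project("projA", seed=1)
        store.add_project("projB", seed=2)
        pids = sorted({r[1] for r in data[store.catalogue.resolve("toy0").dataset_id]})[:3]
        a = commit_cohort(store, self._definition(store, pids), "projA")
        b = commit_cohort(store, self._definition(store, pids), "projB")
        for pid in pids:
            assert a.release_map[pid] != b.release_map[pid]

    def test_empty_cohort_commits_with_warning(self, tmp_path):
        store, _ = toy_store(tmp_path, n_datasets=1)
        store.add_project("proj1", seed=101)
        cohort = commit_cohort(store, self._definition(store, ["NOBODY"]), "proj1")
        assert cohort.members == frozenset()
        assert cohort.warnings

    def test_unknown_project_rejected(self, tmp_path):
        store, _ = toy_store(tmp_path, n_datasets=1)
        with pytest.raises(CohortError):
            commit_cohort(store, self._definition(store, ["P1"]), "ghost-project")

    def test_minting_deterministic_in_seed(self, tmp_path):
        stores = []
        for _ in range(2):
            store, data = toy_store(tmp_path, n_datasets=1)
            store.add_project("proj1", seed=77)
            pids = sorted({r[1] for r in data[store.catalogue.resolve("toy0").dataset_id]})[:4]
            cohort = commit_cohort(store, self._definition(store, pids), "proj1", committed_at=datetime(2016, 6, 1))
            stores.append(cohort.release_map)
        assert stores[0] == stores[1]


class TestDescribe:
    def test_single_block_rendering(self, tmp_path):
        store, _ = toy_store(tmp_path, n_datasets=1)
        ds = store.catalogue.resolve("toy0").dataset_id
        definition = CohortDefinition(
            "d1",
            DatasetLeaf(ds, FilterContainer("AND", [FilterBlock("f1", ds, "g", "equals", {"value": "A"}, "group A")])),
        )
        text = describe_definition(definition, store.catalogue)
        assert "f1" in text and "group A" in text and "toy0" in text

    def test_rendering_is_deterministic(self, tmp_path):
        store, _ = toy_store(tmp_path, n_datasets=1)
        ds = store.catalogue.resolve("toy0").dataset_id
        definition = CohortDefinition(
            "d1",
            SetOpNode(
                "EXCEPT",
                [
                    DatasetLeaf(ds, FilterContainer("AND", [FilterBlock("f1", ds, "g", "equals", {"value": "A"})])),
                    DatasetLeaf(ds, FilterContainer("OR", [FilterBlock("f2", ds, "x", "between", {"lower": 1, "upper": 2})])),
                ],
            ),
        )
        assert describe_definition(definition) == describe_definition(definition)

    def test_every_filter_id_appears(self, tmp_path):
        store, _ = toy_store(tmp_path)
        ids = store.catalogue.dataset_ids()
        blocks = [FilterBlock(f"f{i}", ids[i % len(ids)], "g", "equals", {"value": "A"}) for i in range(5)]
        definition = CohortDefinition(
            "d1",
            SetOpNode(
                "UNION",
                [DatasetLeaf(b.dataset_id, FilterContainer("AND", [b])) for b in blocks],
            ),
        )
        text = describe_definition(definition)
        for b in blocks:
            assert b.filter_id in text

    def test_serialisation_round_trip(self, tmp_path):
        store, _ = toy_store(tmp_path)
        ids = store.catalogue.dataset_ids()
        definition = CohortDefinition(
            "d1",
            SetOpNode(
                "INTERSECT",
                [
                    DatasetLeaf(ids[0], FilterContainer("AND", [FilterBlock("f1", ids[0], "g", "equals", {"value": "A"})])),
                    DatasetLeaf(ids[1], FilterContainer("OR", [FilterBlock("f2", ids[1], "x", "between", {"lower": 0, "upper": 9})])),
                ],
            ),
            "two-way intersection",
        )
        again = CohortDefinition.from_dict(definition.to_dict())
        assert again.to_dict() == definition.to_dict()
        assert evaluate_definition(store, again) == evaluate_definition(store, definition)
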