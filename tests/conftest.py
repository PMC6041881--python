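import csv
import sys
from datetime import datetime
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).resolve().parent))

from rdmlite import Catalogue, Store, ValidationRuleSpec
from rdmlite.synth import WorldConfig, generate_world


def write_csv(path, header, rows):
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        if header is not None:
            writer.writerow(header)
        writer.writerows(rows)
    return str(path)


@pytest.fixture
def demography_store():
    """A store with a small demography-like dataset registered, no data."""
    cat = Catalogue()
    entry = cat.register_dataset(
        "demography",
        [("chi", "code"), ("sex", "code"), ("dob", "date"), ("sbp", "integer")],
        ["chi"],
    )
    cat.set_column_metadata(entry.dataset_id, "chi", category="Internal", role="identifier")
    cat.attach_validation_rule(
        entry.dataset_id, "sbp", ValidationRuleSpec("bounds", {"lower": 0, "upper": 300}, "invalidates_row")
    )
    store = Store(cat)
    return store, entry


@pytest.fixture(scope="session")
def default_world(tmp_path_factory):
    """One default synthetic world shared by read-only tests."""
    out = tmp_path_factory.mktemp("world")
    world = generate_world(WorldConfig(seed=7), str(out))
    return world


@pytest.fixture(scope="session")
def default_store(default_world):
    return default_world.build_store()


def t(day, hour=0):
    return datetime(2016, 1, day, hour)
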