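import importlib.resources as resources

import numpy as np
import pytest

import microviz as mv

STOOL_FIXTURE = "stool_consensus_reference.tsv"
MUCOSA_FIXTURE = "mucosa_consensus_reference.tsv"


def fixture_path(name: str):
    return resources.files("microviz") / "data" / name


@pytest.fixture(scope="session")
def stool_reference():
    import pandas as pd

    return pd.read_csv(fixture_path(STOOL_FIXTURE), sep="\t", dtype={"otu_id": str})


@pytest.fixture(scope="session")
def mucosa_reference():
    import pandas as pd

    return pd.read_csv(fixture_path(MUCOSA_FIXTURE), sep="\t", dtype={"otu_id": str})


@pytest.fixture(scope="session")
def default_sim():
    """One default-condition simulated study, shared across tests."""
    table, meta, truth = mv.simulate_study(mv.SimConfig(seed=11))
    return table, meta, truth


@pytest.fixture
def toy_table():
    counts = np.array([[10, 0, 3], [5, 20, 3], [0, 5, 4]], dtype=np.int64)
    return mv.OtuTable(
        otu_ids=["a", "b", "c"],
        sample_ids=["s1", "s2", "s3"],
        counts=counts,
        taxonomy={
            "a": mv.parse_taxonomy_string("Bacteria1.0Firmicutes0.95GenusA0.9"),
            "b": mv.parse_taxonomy_string("Bacteria1.0Firmicutes0.95GenusB0.9"),
            "c": mv.parse_taxonomy_string("Bacteria1.0Bacteroidetes0.99GenusC0.9"),
        },
    )
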