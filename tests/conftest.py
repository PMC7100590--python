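import numpy as np
import pandas as pd
import pytest

from metatracker.synthdata import generate_study
from metatracker.tables_io import FeatureTable


@pytest.fixture
def small_table() -> FeatureTable:
    """4 taxa x 3 samples with distinct column sums."""
    data = pd.DataFrame(
        {
            "s1": [5, 0, 3, 2],
            "s2": [1, 4, 0, 0],
            "s3": [0, 0, 7, 1],
        },
        index=["tA", "tB", "tC", "tD"],
    )
    return FeatureTable(data)


@pytest.fixture
def small_metadata() -> pd.DataFrame:
    meta = pd.DataFrame(
        {"env": ["soil", "soil", "water"], "role": ["source", "source", "sink"]},
        index=["s1", "s2", "s3"],
    )
    meta.index.name = "sample_id"
    return meta


@pytest.fixture(scope="session")
def fixture_lineage_map() -> dict[str, str]:
    """50 taxa with known domains, one lineage string per taxon."""
    domains = ["Bacteria", "Archaea", "Eukaryota", "Viruses"]
    return {
        f"genus{i:02d}": f"sk:{domains[i % 4]};p:phylum{i};g:genus{i:02d}"
        for i in range(50)
    }


@pytest.fixture(scope="session")
def mini_study():
    """Tiny 2-environment study for fast end-to-end tests."""
    return generate_study("mini", seed=3)


@pytest.fixture(scope="session")
def coastal_study():
    """Default-preset study (5 envs, 14 sinks, known mixing truth)."""
    return generate_study("coastal-small", seed=5)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
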