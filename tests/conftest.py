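import pandas as pd
import pytest

from nsafde import SpectralCountMatrix
from nsafde.datasets import (
    control_fixture_matrix,
    fixture_matrix,
    leukocyte_control_comparison,
    neat_semen_comparison,
    processed_semen_comparison,
)


def make_matrix(counts: dict, groups: dict, lengths: dict | None = None) -> SpectralCountMatrix:
    """Small helper: counts maps run_id -> {accession: count}; groups maps
    run_id -> (group, replicate)."""
    count_frame = pd.DataFrame(counts).fillna(0.0)
    count_frame.index.name = "accession"
    accessions = count_frame.index
    proteins = pd.DataFrame(
        {
            "gene": [f"G_{a}" for a in accessions],
            "description": ["" for _ in accessions],
            "length": [(lengths or {}).get(a, 100) for a in accessions],
        },
        index=accessions,
    )
    design = pd.DataFrame(
        [{"run_id": r, "group": g, "replicate": rep} for r, (g, rep) in groups.items()]
    ).set_index("run_id")
    return SpectralCountMatrix(proteins=proteins, counts=count_frame, design=design)


@pytest.fixture(scope="session")
def neat_table():
    return neat_semen_comparison()


@pytest.fixture(scope="session")
def processed_table():
    return processed_semen_comparison()


@pytest.fixture(scope="session")
def control_table():
    return leukocyte_control_comparison()


@pytest.fixture(scope="session")
def neat_fixture(neat_table):
    return fixture_matrix(neat_table)


@pytest.fixture(scope="session")
def processed_fixture(processed_table):
    return fixture_matrix(processed_table)


@pytest.fixture(scope="session")
def control_fixture(control_table):
    return control_fixture_matrix(control_table)
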