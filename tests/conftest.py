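from pathlib import Path

import pandas as pd
import pytest

from swathcomp import (
    AbundanceMatrix,
    Design,
    SimulationConfig,
    simulate_dataset,
)

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def small_dataset():
    """150-gene four-species dataset at default noise, shared across tests."""
    return simulate_dataset(SimulationConfig(seed=11, n_genes=150))


@pytest.fixture(scope="session")
def fixture_matrix() -> AbundanceMatrix:
    """The frozen 50-gene x 20-sample log2 matrix (generated at seed 1)."""
    df = pd.read_csv(DATA_DIR / "moderated_t_fixture.tsv", sep="\t", index_col="feature")
    return AbundanceMatrix(df, scale="log2")


@pytest.fixture(scope="session")
def fixture_design(fixture_matrix) -> Design:
    cols = fixture_matrix.samples
    table = pd.DataFrame(
        {
            "sample_id": cols,
            "species": ["specA"] * 10 + ["specB"] * 10,
            "group": ["A"] * 10 + ["B"] * 10,
        }
    )
    return Design(table, contrast=("A", "B"))


def make_design(samples_by_species: dict[str, list[str]], group_of: dict[str, str], contrast):
    rows = []
    for sp, samples in samples_by_species.items():
        for s in samples:
            rows.append({"sample_id": s, "species": sp, "group": group_of[sp]})
    return Design(pd.DataFrame(rows), contrast=contrast)
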