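import numpy as np
import pandas as pd
import pytest

from tnftime.datasets import CountDataset
from tnftime.simulate import SyntheticConfig, generate_dataset


@pytest.fixture(scope="session")
def small_sim():
    """300-gene dataset with the default archetype mix (both sexes)."""
    return generate_dataset(SyntheticConfig(n_genes=300, seed=101))


@pytest.fixture(scope="session")
def null_sim():
    """All-null 400-gene dataset for specificity/calibration checks."""
    return generate_dataset(
        SyntheticConfig(n_genes=400, seed=202, archetype_mix={"null": 1.0})
    )


@pytest.fixture(scope="session")
def block_sim():
    """600 genes with planted coexpression blocks (150/120/80/10) + noise."""
    return generate_dataset(
        SyntheticConfig(
            n_genes=600,
            seed=303,
            archetype_mix={"null": 1.0},
            coexpression_blocks=(150, 120, 80, 10),
        )
    )


@pytest.fixture()
def tiny_dataset():
    """Hand-built 3-gene x 4-sample dataset for IO and container tests."""
    counts = pd.DataFrame(
        [[5, 8, 0, 3], [10, 20, 30, 40], [100, 80, 120, 90]],
        index=["gA", "gB", "gC"],
        columns=["s1", "s2", "s3", "s4"],
    )
    samples = pd.DataFrame(
        {
            "condition": ["control", "treated", "control", "treated"],
            "time_h": [0.5, 0.5, 72.0, 72.0],
            "pool": ["P1", "P1", "P1", "P1"],
            "sex": ["F", "F", "F", "F"],
        },
        index=counts.columns,
    )
    genes = pd.DataFrame(
        {
            "symbol": ["A", "B", "C"],
            "biotype": ["protein_coding"] * 3,
            "length_bp": [1000, 2000, 500],
        },
        index=counts.index,
    )
    return CountDataset(counts=counts, samples=samples, genes=genes)
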