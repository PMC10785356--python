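import numpy as np
import pandas as pd
import pytest

import pathact as pa
from pathact.expression import NORMAL, TUMOUR


@pytest.fixture
def tiny_dataset() -> pa.ExpressionDataset:
    """3 genes x 6 samples (3 normal / 3 tumour) with hand-checkable values."""
    values = pd.DataFrame(
        {
            "S1": [1.0, 1.0, 5.0],
            "S2": [2.0, 2.0, 5.0],
            "S3": [3.0, 3.0, 5.0],
            "S4": [2.0, 3.0, 5.0],
            "S5": [3.0, 2.0, 5.0],
            "S6": [4.0, 1.0, 5.0],
        },
        index=["GA", "GB", "GC"],
    )
    labels = pd.Series(
        [NORMAL, NORMAL, NORMAL, TUMOUR, TUMOUR, TUMOUR], index=values.columns
    )
    return pa.ExpressionDataset(values, labels)


@pytest.fixture
def random_dataset() -> pa.ExpressionDataset:
    """40 genes x 20 samples of pure noise, fixed seed."""
    rng = np.random.default_rng(42)
    genes = [f"G{i:03d}" for i in range(40)]
    samples = [f"S{i:02d}" for i in range(20)]
    values = pd.DataFrame(rng.normal(size=(40, 20)), index=genes, columns=samples)
    labels = pd.Series([NORMAL] * 10 + [TUMOUR] * 10, index=samples)
    return pa.ExpressionDataset(values, labels)


@pytest.fixture(scope="session")
def small_benchmark():
    """A small but complete synthetic benchmark shared across tests."""
    design = pa.SyntheticDesign(
        n_genes=300,
        n_samples=(30, 30),
        n_pathways=30,
        pathway_size=(8, 15),
        n_risk_pathways=5,
        effect_size=1.5,
        edges_per_gene=3.0,
        seed=11,
    )
    dataset, sets, network, truth = pa.generate_dataset(design)
    return {
        "design": design,
        "dataset": dataset,
        "sets": pa.restrict_to_dataset(sets, dataset),
        "network": network,
        "truth": truth,
    }
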