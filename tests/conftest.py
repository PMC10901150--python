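import warnings

import numpy as np
import pandas as pd
import pytest

from toxmodnet.containers import LogFCMatrix
from toxmodnet.design import generate_design
from toxmodnet.presets import (
    standard_network_dataset,
    standard_preservation_experiment,
    standard_rnai_screen,
    standard_trait_screen,
)

warnings.filterwarnings("ignore", category=UserWarning)


@pytest.fixture(scope="session")
def small_design():
    """1 DILI compound, 6 doses, 3 time points, 3 replicates, 1 batch."""
    return generate_design({"DILI": 1}, n_dose_levels=6, time_points=(4, 8, 24),
                           n_replicates=3, n_batches=1, seed=7)


@pytest.fixture(scope="session")
def network_dataset():
    """Standard 2,000-gene planted-module dataset, seed 1 (shared, heavy)."""
    return standard_network_dataset(seed=1)


@pytest.fixture(scope="session")
def trait_screen():
    return standard_trait_screen(seed=1)


@pytest.fixture(scope="session")
def preservation_experiment():
    return standard_preservation_experiment(seed=1)


@pytest.fixture(scope="session")
def rnai_screen():
    return standard_rnai_screen(seed=1, effect_size=3.0)


def random_logfc(rng, n_conditions=12, n_genes=8, prefix="C") -> LogFCMatrix:
    """Small random log2FC matrix with uniform padj, for oracle tests."""
    idx = pd.MultiIndex.from_tuples(
        [(f"{prefix}{i}", 1 + i % 3, (4, 8, 24)[i % 3]) for i in range(n_conditions)],
        names=("compound", "dose_level", "time_h"),
    )
    genes = pd.Index([f"g{j:02d}" for j in range(n_genes)], name="gene")
    values = pd.DataFrame(rng.normal(size=(n_conditions, n_genes)), index=idx, columns=genes)
    padj = pd.DataFrame(rng.uniform(size=(n_conditions, n_genes)), index=idx, columns=genes)
    return LogFCMatrix(values=values, padj=padj)
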