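import numpy as np
import pandas as pd
import pytest

from chemolib import (BioactivityTable, SynthLibraryConfig, SynthScreenConfig,
                      synth_bioactivity, synth_screen)


def random_bioactivity_table(rng: np.random.Generator,
                             n_rows: int = 400,
                             n_compounds: int = 80,
                             n_targets: int = 12) -> BioactivityTable:
    """A random long-format bioactivity table with continuous potencies."""
    assays = np.array(["IC50", "EC50", "Ki", "Kd"])
    df = pd.DataFrame({
        "compound_id": [f"C{i}" for i in rng.integers(0, n_compounds, n_rows)],
        "target_id": [f"T{i}" for i in rng.integers(0, n_targets, n_rows)],
        "assay_type": assays[rng.integers(0, 4, n_rows)],
        "value_nM": 10.0 ** rng.uniform(0, 5, n_rows),
    })
    return BioactivityTable(df)


@pytest.fixture(scope="session")
def small_library():
    """One modest planted-redundancy library shared across tests."""
    return synth_bioactivity(SynthLibraryConfig(
        n_compounds=300, n_targets=25, n_redundant_clusters=10,
        cluster_size=10, seed=11))


@pytest.fixture(scope="session")
def small_screen():
    """One modest synthetic screen (2 patients) shared across tests."""
    return synth_screen(SynthScreenConfig(n_patients=2, n_compounds=150,
                                          seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
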