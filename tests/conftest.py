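import numpy as np
import pandas as pd
import pytest

from tadscope import CountMatrix, simulate_study
from tadscope.config import SimulationConfig, default_config


@pytest.fixture(scope="session")
def default_study():
    """The default synthetic study (3 patients, 2 chroms, 3 loci) at a fixed seed."""
    return simulate_study(default_config(seed=7))


@pytest.fixture(scope="session")
def flat_sim_config():
    """A small flat simulation (no TADs/loci/modules) for DE-level tests."""
    return SimulationConfig(
        seed=3,
        n_mrna=400,
        n_lnc=0,
        n_mir=0,
        de_fraction_per_class=0.1,
        dispersion=0.1,
        n_modules=0,
        tad_plan=[],
        loci_plan=[],
    )


@pytest.fixture()
def toy_count_matrix():
    """Hand-sized paired count matrix: 5 features x 2 patients x 2 conditions."""
    counts = pd.DataFrame(
        {
            "P1_normal": [10, 100, 40, 7, 0],
            "P1_lesion": [12, 95, 160, 6, 3],
            "P2_normal": [9, 110, 45, 8, 2],
            "P2_lesion": [11, 105, 170, 9, 4],
        },
        index=[f"g{i}" for i in range(5)],
    )
    design = pd.DataFrame(
        {
            "sample": counts.columns,
            "patient": ["P1", "P1", "P2", "P2"],
            "condition": ["normal", "lesion", "normal", "lesion"],
        }
    )
    class_of = pd.Series("mRNA", index=counts.index)
    return CountMatrix(counts, design, class_of)


def random_symmetric_adjacency(rng, n):
    a = rng.uniform(0, 1, size=(n, n))
    a = (a + a.T) / 2
    np.fill_diagonal(a, 0.0)
    return a
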