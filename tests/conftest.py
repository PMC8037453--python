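import numpy as np
import pandas as pd
import pytest

from chromotx import synthetic_data as sd
from chromotx.annotation_io import CountsMatrix


@pytest.fixture(scope="session")
def tiny_cohort():
    """Two-group cohort (A-like vs CTRL) small enough for every unit test."""
    cfg = sd.small_config(
        seed=11,
        group_sizes={"A": 20, "CTRL": 20},
        n_normals=12,
        genes_per_arm=20,
        arms=("1p", "1q", "16p", "16q", "2q", "8q"),
    )
    return sd.generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_cohort():
    """All-groups cohort used by the integration-style tests."""
    return sd.generate_cohort(sd.small_config(seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def random_counts(rng):
    """A 30-gene x 8-sample NB count matrix with mild library variation."""
    genes = [f"g{i:03d}" for i in range(30)]
    samples = [f"s{j}" for j in range(8)]
    base = rng.gamma(2.0, 50.0, size=(30, 1))
    lib = rng.uniform(0.5, 2.0, size=8)
    mean = base * lib
    counts = rng.poisson(rng.gamma(5.0, mean / 5.0))
    return CountsMatrix(pd.DataFrame(counts, index=genes, columns=samples))
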