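import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import ppskit as pk

settings.register_profile(
    "ci",
    derandomize=True,
    database=None,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def tiny_genotypes() -> pk.GenotypeMatrix:
    """6 subjects x 3 SNPs, all categories represented, no missing."""
    data = pd.DataFrame(
        {
            "rs1": [1, 1, 2, 2, 3, 3],
            "rs2": [1, 2, 1, 2, 1, 2],
            "rs3": [3, 3, 1, 1, 2, 2],
        },
        index=[f"S{i}" for i in range(1, 7)],
        dtype=float,
    )
    return pk.GenotypeMatrix(data)


@pytest.fixture
def tiny_outcome(tiny_genotypes) -> pk.OutcomeData:
    return pk.OutcomeData(
        delta_sse=pd.Series([0, 1, 1, 2, 3, 5], index=tiny_genotypes.data.index)
    )


def random_cohort(rng: np.random.Generator, n_subjects: int, n_snps: int):
    """Small random cohort for oracle-equivalence fixtures."""
    cats = rng.integers(1, 4, size=(n_subjects, n_snps)).astype(float)
    g = pk.genotype_matrix_from_arrays(
        cats,
        [f"S{i}" for i in range(n_subjects)],
        [f"rs{j}" for j in range(n_snps)],
    )
    delta = pd.Series(rng.integers(-4, 7, size=n_subjects), index=g.data.index)
    return g, pk.OutcomeData(delta_sse=delta)
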