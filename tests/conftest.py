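import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import mechanoseq as ms

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def toy_counts() -> ms.CountMatrix:
    """3 genes x 4 samples, hand-sized for exact computations."""
    df = pd.DataFrame(
        {
            "s1": [10, 20, 30],
            "s2": [15, 25, 35],
            "s3": [5, 50, 45],
            "s4": [8, 16, 24],
        },
        index=pd.Index(["g1", "g2", "g3"], name="gene_id"),
    )
    return ms.CountMatrix(df)


@pytest.fixture
def balanced_design() -> ms.DesignTable:
    rows = []
    for genotype in ("KDEL", "SUN1L"):
        for rigidity in ("soft", "stiff"):
            for rep in (1, 2, 3):
                rows.append((f"{genotype}_{rigidity}_r{rep}",
                             rigidity, genotype, "none", rep))
    return ms.DesignTable(pd.DataFrame(
        rows, columns=["sample_id", "rigidity", "genotype", "treatment", "replicate"]
    ))


@pytest.fixture(scope="session")
def small_simulation():
    """One seeded simulated dataset shared by the slower integration tests."""
    cfg = ms.SimulationConfig(n_genes=400, seed=123)
    counts, design, truth = ms.simulate_counts(cfg)
    return counts, design, truth.set_index("gene_id")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260926)
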