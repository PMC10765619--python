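import numpy as np
import pytest

from sweepibd.io import GenotypeMatrix, PopulationPanel
from sweepibd.syndata import SimConfig, simulate_scenario


@pytest.fixture(scope="session")
def scenario():
    """Default crossbred scenario with the implanted sweep (seed 1)."""
    return simulate_scenario(SimConfig(seed=1))


@pytest.fixture(scope="session")
def scenario_with_failures():
    """Scenario with truth-flagged failing records and missing calls."""
    return simulate_scenario(SimConfig(seed=7, fail_fraction=0.3, missing_rate=0.02))


@pytest.fixture
def two_pop_panel():
    return PopulationPanel(
        samples=[f"A_{i}" for i in range(4)] + [f"B_{i}" for i in range(4)],
        population_of={
            **{f"A_{i}": "A" for i in range(4)},
            **{f"B_{i}": "B" for i in range(4)},
        },
    )


def matrix_from_dosage(dosage, panel, pos0=None, chrom="1"):
    """Build a GenotypeMatrix from a raw dosage array (test helper)."""
    dosage = np.asarray(dosage, dtype=np.int8)
    n = dosage.shape[0]
    if pos0 is None:
        pos0 = np.arange(n) * 100
    return GenotypeMatrix(
        chrom=np.array([chrom] * n, dtype=object),
        pos0=np.asarray(pos0, dtype=np.int64),
        ref=np.array(["A"] * n, dtype=object),
        alt=np.array(["G"] * n, dtype=object),
        dosage=dosage,
        panel=panel,
    )
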