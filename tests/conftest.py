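import numpy as np
import pandas as pd
import pytest

from exomir.qpcr_io import CtMatrix
from exomir.synthetic_data import (
    SimulationConfig,
    simulate_profiling_pairs,
    simulate_validation_cohort,
)


def make_matrix(
    ct,
    assays,
    samples,
    censored=None,
    plates=None,
    assay_class=None,
) -> CtMatrix:
    """Build a CtMatrix from plain nested lists, for hand-crafted fixtures."""
    ct = pd.DataFrame(np.asarray(ct, dtype=float), index=assays, columns=samples)
    if censored is None:
        cen = ct.isna()
    else:
        cen = pd.DataFrame(np.asarray(censored, dtype=bool), index=assays, columns=samples)
    return CtMatrix(
        ct=ct,
        censored=cen,
        plate_of_sample=plates or {},
        assay_class=assay_class or {},
    )


@pytest.fixture(scope="session")
def sim_profiling():
    """Default-condition profiling simulation (752 assays, 3 pairs)."""
    cfg = SimulationConfig(seed=11)
    m, pairs, truth = simulate_profiling_pairs(cfg)
    return cfg, m, pairs, truth


@pytest.fixture(scope="session")
def sim_validation():
    """Default-condition validation cohort (31 vs 52)."""
    cfg = SimulationConfig(seed=11)
    m, table, truth = simulate_validation_cohort(cfg)
    return cfg, m, table, truth
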