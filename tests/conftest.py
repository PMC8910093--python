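import numpy as np
import pandas as pd
import pytest

import liqrad as lq


@pytest.fixture(scope="session")
def small_cohort() -> pd.DataFrame:
    return lq.generate_cohort(lq.CohortConfig(n_patients=8, seed=11))


@pytest.fixture(scope="session")
def balanced_cohort() -> pd.DataFrame:
    """Six patients with exactly 100 CTCs each (600 cells total)."""
    cfg = lq.CohortConfig(n_patients=6, zero_inflation=0.0, seed=21)
    cohort = lq.generate_cohort(cfg)
    return cohort.assign(rarecyte_count=np.full(len(cohort), 100))


def make_mixture(k_true, n_features=20, separation=10.0, seed=0, coupling=0.0,
                 cohort=None):
    """Standardize-ready mixture with known labels."""
    if cohort is None:
        cfg = lq.CohortConfig(n_patients=6, zero_inflation=0.0, seed=1000 + seed)
        cohort = lq.generate_cohort(cfg).assign(rarecyte_count=100)
    matrix, truth = lq.generate_ctc_features(
        cohort,
        lq.ClusterSpec(
            k_true=k_true,
            n_features=n_features,
            separation=separation,
            prevalence_coupling=coupling,
            seed=2000 + seed,
        ),
    )
    morpho = matrix.select_features(
        [c for c in matrix.data.columns if not c.startswith("mfi_")]
    )
    return morpho, truth
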