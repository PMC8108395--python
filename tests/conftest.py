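import numpy as np
import pandas as pd
import pytest

from edtwin.synthetic import SimConfig, simulate_bivariate, simulate_continuous


@pytest.fixture(scope="session")
def study_cohort() -> pd.DataFrame:
    """One study-sized AE cohort (768 MZ + 713 DZ pairs, h2 = 0.65)."""
    return simulate_continuous(SimConfig(seed=11))


@pytest.fixture(scope="session")
def large_cohort() -> pd.DataFrame:
    """Large AE cohort for asymptotic checks."""
    return simulate_continuous(SimConfig(n_mz=30_000, n_dz=30_000, seed=7))


@pytest.fixture(scope="session")
def oed_bivariate_cohort() -> pd.DataFrame:
    """Study-sized mixed cohort: continuous score + 3.3%-prevalence trait
    with genetic/non-shared-environment cross-trait correlations 0.52."""
    cfg = SimConfig(a2_2=0.67, c2_2=0.0, e2_2=0.33, rA=0.52, rC=0.0, rE=0.52,
                    prevalence=0.033, seed=42)
    return simulate_bivariate(cfg)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
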