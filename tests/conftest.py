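import numpy as np
import pandas as pd
import pytest

from drugsig import simulate
from drugsig.signatures import (SignatureDerivationParams, derive_signature,
                                resample_correlations)

#: fixed seed for all seeded randomness in the suite
SEED = 101


@pytest.fixture(scope="session")
def study_config() -> simulate.SyntheticConfig:
    """The default study conditions: 1000 genes, 60 samples, 20+20 planted
    genes at effect size 1.5 with expression noise SD 0.3."""
    return simulate.SyntheticConfig(seed=SEED)


@pytest.fixture(scope="session")
def cohort(study_config):
    return simulate.generate_cohort(study_config)


@pytest.fixture(scope="session")
def derived_signature(cohort):
    """Signature derived from the session cohort with 200 resampling runs."""
    params = SignatureDerivationParams(n_resamples=200, seed=SEED)
    freq = resample_correlations(cohort.expression,
                                 cohort.response.iloc[:, 0], params)
    return derive_signature(freq, params, drug_id="drug_1")


@pytest.fixture(scope="session")
def truth_signature(cohort):
    """Planted ground-truth signature (no derivation noise)."""
    from drugsig.signatures import DrugEfficacySignature
    t = cohort.truth
    return DrugEfficacySignature(
        drug_id="drug_1", up_genes=list(t.planted_up_genes),
        down_genes=list(t.planted_down_genes), frequencies=pd.DataFrame())


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(SEED)
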