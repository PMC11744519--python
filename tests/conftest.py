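import numpy as np
import pytest

import itesurv as its


@pytest.fixture(scope="session")
def cohort5k():
    """Default heterogeneous scenario, n=5000."""
    cfg = its.default_config(n_patients=5000, seed=11)
    cohort, truth = its.generate_cohort(cfg)
    return cfg, cohort, truth


@pytest.fixture(scope="session")
def encoded5k(cohort5k):
    cfg, cohort, truth = cohort5k
    enc = its.CovariateEncoder(cfg.covariates).fit(cohort)
    return enc, enc.transform(cohort)


@pytest.fixture(scope="session")
def linear_fit5k(cohort5k, encoded5k):
    """Correctly specified linear balanced T-learner (alpha = 0)."""
    cfg, cohort, truth = cohort5k
    enc, X = encoded5k
    spec = its.BalancedTLearnerSpec(seed=0)
    return its.fit_balanced_tlearner(
        X, cohort["arm"], cohort["time"], cohort["event"], spec,
        feature_names=enc.feature_names_,
    )


@pytest.fixture(scope="session")
def cohort10k():
    cfg = its.default_config(n_patients=10000, seed=13)
    cohort, truth = its.generate_cohort(cfg)
    return cfg, cohort, truth
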