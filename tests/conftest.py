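import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import clustmed as cm
from clustmed.gee import GEEFit, ModelSpec
from clustmed.synthetic import CONFOUNDERS

settings.register_profile("suite", derandomize=True, max_examples=40)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def confounders():
    return list(CONFOUNDERS)


@pytest.fixture(scope="session")
def small_cohort():
    """One moderate synthetic cohort (150 families, 3 mediators) + truth."""
    cfg = cm.default_config(seed=11, n_families=150, n_mediators=3)
    cohort, truth = cm.simulate_cohort(cfg)
    return cfg, cohort, truth


@pytest.fixture(scope="session")
def analysis_sample(small_cohort):
    """The same cohort after exclusions and mediator preprocessing."""
    cfg, cohort, truth = small_cohort
    sample, _ = cm.build_analysis_sample(cohort, cfg.mediator_names)
    sample, _ = cm.preprocess_mediators(sample, cfg.mediator_names)
    return cfg, sample, truth


def make_fit(response, coefs, cluster="family_id"):
    """Fabricate a GEEFit carrying given coefficients (for arithmetic tests)."""
    names = [k for k in coefs if k != "Intercept"]
    params = pd.Series({"Intercept": coefs.get("Intercept", 0.0),
                        **{k: coefs[k] for k in names}})
    return GEEFit(
        spec=ModelSpec(response, tuple(names), cluster),
        params=params,
        robust_se=pd.Series(1.0, index=params.index),
        rho=0.0, scale=1.0, n_obs=10, n_clusters=5,
        converged=True, n_iter=1,
    )
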