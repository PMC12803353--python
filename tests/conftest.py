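import numpy as np
import pandas as pd
import pytest

from ratiomap import preprocess as pp
from ratiomap import synthdata as sd


@pytest.fixture(scope="session")
def small_cohort():
    """2,000-sample cohort with one variant of each scenario, 6 traits."""
    traits = [f"T{i+1}" for i in range(6)]
    specs = [
        sd.VariantSpec("v_opp", 0.3, "opposed", 0.15, 0.15, ("T1", "T2")),
        sd.VariantSpec("v_conf", 0.3, "confounded", 0.10, 0.0, ("T3", "T4")),
        sd.VariantSpec("v_null", 0.3),
    ]
    geno = sd.simulate_genotypes(2000, specs, seed=11)
    config = sd.CohortConfig(
        n_samples=2000, n_traits=6, lam=1.0, sigma_trait=0.2,
        sigma_confounder=0.5, seed=12, trait_names=traits,
        na_rate=0.0, zero_rate=0.0,
    )
    panel, covariates, truth = sd.simulate_cohort(geno, specs, config)
    return dict(specs=specs, geno=geno, panel=panel, covariates=covariates,
                truth=truth, traits=traits, config=config)


@pytest.fixture(scope="session")
def logged_panel(small_cohort):
    return pp.log_transform(pp.zeros_to_missing(small_cohort["panel"]))


@pytest.fixture
def rng():
    return np.random.default_rng(2026)
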