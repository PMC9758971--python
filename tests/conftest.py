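import numpy as np
import pandas as pd
import pytest

import ecoglmm as eg


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def make_poisson_glmm_frame(n_groups=10, n_per=20, beta=(1.0, 0.5),
                            sigma_b=0.5, seed=0, taxon="t1"):
    """Single-covariate Poisson GLMM data with known truth."""
    rng = np.random.default_rng(seed)
    x = rng.normal(0.0, 1.0, n_groups * n_per)
    groups = np.repeat(np.arange(n_groups), n_per)
    b = rng.normal(0.0, sigma_b, n_groups)
    mu = np.exp(beta[0] + beta[1] * x + b[groups])
    y = rng.poisson(mu)
    df = pd.DataFrame({
        "site": [f"s{g:02d}" for g in groups],
        "night": [f"n{i:04d}" for i in range(len(x))],
        "taxon": taxon,
        "count": y,
        "x": x,
    })
    return eg.CountTable(df)


@pytest.fixture
def small_glmm_table():
    return make_poisson_glmm_frame()


@pytest.fixture(scope="session")
def bat_table():
    """One draw from the default campaign design (840 site-nights, 7 taxa)."""
    table, truth = eg.generate(eg.default_bat_design(seed=0), seed=0)
    return table, truth


@pytest.fixture(scope="session")
def bat_formula():
    covs = ["year", "moon_illum", "ordinal_date", "elevation",
            "structure_index", "prop_cool_lights", "brightness_index",
            "water_distance", "prop_developed", "prop_forest"]
    formula = "~ " + " + ".join(covs)
    standardize = tuple(c for c in covs if c != "year")
    return formula, standardize
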