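import numpy as np
import pandas as pd
import pytest

from pneumorisk import GeneratorConfig, generate_covariates, make_geometry, simulate_counts


@pytest.fixture(scope="session")
def small_table():
    """An 18-district covariate table with simulated counts (fixed seed)."""
    cfg = GeneratorConfig(seed=11)
    table = generate_covariates(cfg)
    return simulate_counts(table, cfg.coefficients, seed=12,
                           target_mean_count=cfg.target_mean_count)


@pytest.fixture(scope="session")
def unit_square_polygons():
    return make_geometry(4, (0.0, 0.0, 1.0, 1.0), seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
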