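import numpy as np
import pandas as pd
import pytest

import rejuvenomics as rj


@pytest.fixture(scope="session")
def small_methylome():
    """A small planted methylome dataset shared across tests."""
    cfg = rj.SynthMethylConfig(n_regions=120, seed=101)
    table, regions, sheet, truth = rj.generate_methylome(cfg)
    return cfg, table, regions, sheet, truth


@pytest.fixture(scope="session")
def small_expression():
    """A small planted expression dataset shared across tests."""
    cfg = rj.SynthExprConfig(n_genes=600, n_sets=12, set_size=10, seed=202)
    expr, sets, sheet, truth = rj.generate_expression(cfg)
    return cfg, expr, sets, sheet, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def two_group_expr(rng):
    """Null Gaussian 5v5 expression frame for gene-score tests."""
    x = rng.normal(size=(300, 10))
    expr = pd.DataFrame(
        x, index=[f"g{i}" for i in range(300)], columns=[f"s{i}" for i in range(10)]
    )
    groups = pd.Series(["young"] * 5 + ["old"] * 5, index=expr.columns)
    return expr, groups
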