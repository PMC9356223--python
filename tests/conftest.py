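import numpy as np
import pandas as pd
import pytest

from ionoflux.simulate import (
    CountSimConfig,
    IonomeSimConfig,
    gen_count_matrix,
    gen_ionome_dataset,
)


@pytest.fixture(scope="session")
def noiseless_ionome():
    """Zero-noise ionome dataset with all uptake multipliers at 1."""
    cfg = IonomeSimConfig(noise_cv=0.0, seed=11)
    return gen_ionome_dataset(cfg)


@pytest.fixture(scope="session")
def planted_ionome():
    """Zero-noise dataset with a planted Fe multiplier of 0.2 at t2_25."""
    cfg = IonomeSimConfig(noise_cv=0.0, seed=11)
    mult = pd.DataFrame(
        1.0, index=list(cfg.elements), columns=["t1_40", "t1_25", "t2_40", "t2_25"]
    )
    mult.loc["Fe", "t2_25"] = 0.2
    mult.loc["Mo", "t1_25"] = 0.3
    cfg = IonomeSimConfig(noise_cv=0.0, seed=11, uptake_multiplier=mult)
    return gen_ionome_dataset(cfg), mult


@pytest.fixture(scope="session")
def small_counts():
    """A 500-gene NB count matrix with 10% planted DE at |log2FC| = 2."""
    cfg = CountSimConfig(n_genes=500, de_fraction=0.1, planted_log2fc=2.0, seed=5)
    return gen_count_matrix(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
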