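import numpy as np
import pytest

from fieldomics import rlog, simulate


@pytest.fixture(scope="session")
def design62():
    """10x10 grid, 0.5 m spacing, two emergence failures: 62 analysis plants."""
    return simulate.make_field_design(10, 10, 0.5, missing_fraction=0.02, seed=1)


@pytest.fixture(scope="session")
def small_trial():
    """A compact synthetic trial shared by IO/normalization/association tests."""
    cfg = simulate.SimulationConfig(n_genes=60, n_causal_genes=8, seed=7)
    return simulate.simulate_trial(cfg)


@pytest.fixture(scope="session")
def small_rlog(small_trial):
    model = rlog.fit_rlog(small_trial["counts"], small_trial["meta"])
    return model


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
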