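import numpy as np
import pytest

import founderscan as fs


@pytest.fixture(scope="session")
def small_sim_config():
    """A fast two-class configuration for structural tests."""
    return fs.SimConfig(
        n_sites_per_class=120,
        sample_sizes={"founder": 150, "outbred": 150},
        seed=7,
        class_specs=(
            fs.VariantClassSpec("synonymous", s=0.0, h=0.5, q0=(1e-4, 0.05), q0_shape="log"),
            fs.VariantClassSpec("lof", s=0.01, h=0.5, q0=(1e-4, 0.02), q0_shape="log"),
        ),
    )


@pytest.fixture(scope="session")
def small_cohorts(small_sim_config):
    return fs.simulate_cohorts(small_sim_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
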