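import numpy as np
import pytest

from adtransfer import GeneratorConfig, generate_cohorts


@pytest.fixture(scope="session")
def small_generator_config() -> GeneratorConfig:
    """A scaled-down cohort configuration shared by tests that only need
    structure, not the full feature dimensionality."""
    return GeneratorConfig(
        seed=11,
        feature_groups={
            "Grey matter density": 12,
            "Subcortical volumes": 6,
            "Cortical thickness": 10,
            "Fractional anisotropy": 8,
            "Mean diffusivity": 8,
            "Axial diffusivity": 8,
            "Radial diffusivity": 8,
            "Functional connectivity": 15,
            "ALFF": 15,
        },
        n_per_group={"training": {"HC": 60, "AD": 40},
                     "clinic": {"SMC": 36, "MCI": 36, "AD": 36}},
    )


@pytest.fixture(scope="session")
def small_cohorts(small_generator_config):
    return generate_cohorts(small_generator_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
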