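import dataclasses

import pytest

from synfix import (
    DEFAULT_ANGLE_PARAMS,
    DEFAULT_LEVELS_CM,
    CohortConfig,
    LevelParams,
    generate_cohort,
    load_default_config,
    load_packaged_table1,
    make_screw_grid,
)


@pytest.fixture(scope="session")
def default_config():
    return load_default_config()


@pytest.fixture(scope="session")
def table1_cells():
    return load_packaged_table1()


@pytest.fixture(scope="session")
def small_config(default_config):
    return dataclasses.replace(default_config, n_ankles=5, seed=11)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)


@pytest.fixture(scope="session")
def default_grid(default_config):
    return make_screw_grid(default_config.level_heights)


def single_level_config(level_cm=5.0, n_ankles=100, seed=3, **overrides):
    """A one-level configuration using that level's default parameters."""
    idx = DEFAULT_LEVELS_CM.index(level_cm)
    mean, sd = DEFAULT_ANGLE_PARAMS[idx]
    params = dict(
        level_cm=level_cm,
        angle_mean_deg=mean,
        angle_sd_deg=sd,
        artery_mean_offset_mm=2.0,
        artery_sd_mm=1.2,
        min_clearance_mm=0.0,
    )
    params.update(overrides)
    return CohortConfig(
        n_ankles=n_ankles, seed=seed, levels=(LevelParams(**params),)
    )
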