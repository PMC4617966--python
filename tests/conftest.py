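import dataclasses

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pionuc.analysis import run_pipeline
from pionuc.config import RunConfig
from pionuc.simulate import SyntheticConfig, generate_genome

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


SMALL = dict(
    chrom_lengths={"chr1": 200_000, "chr2": 200_000},
    n_enhancers=30,
    n_open_regions=20,
    n_distal_open_regions=15,
    n_control_regions=15,
    n_hot_regions=15,
    mnase_depth=300_000,
    chip_depth=300_000,
    seed=7,
)


def small_config(**overrides) -> SyntheticConfig:
    return SyntheticConfig(**{**SMALL, **overrides})


@pytest.fixture(scope="session")
def small_dataset():
    """A 400 kb synthetic genome with 30 enhancers — the shared fixture for
    stage-level tests."""
    return generate_genome(small_config())


@pytest.fixture(scope="session")
def small_result(small_dataset):
    """Full pipeline run on the small fixture (bins scaled to its region
    count)."""
    cfg = RunConfig(seed=7)
    cfg.bin_size = 10
    return run_pipeline(small_dataset, cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def variant_config(**overrides) -> SyntheticConfig:
    return dataclasses.replace(small_config(), **overrides)
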