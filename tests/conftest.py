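import numpy as np
import pytest

from vambn import FixtureConfig, generate_fixture, small_fixture_config
from vambn.hivae import HivaeConfig, fit_module


@pytest.fixture(scope="session")
def small_cohort():
    """Compact two-module cohort: 150 participants, 4 visits, 6 variables."""
    cfg = small_fixture_config(n_participants=150, n_visits=4, seed=7)
    cohort, truth = generate_fixture(cfg)
    return cohort, truth, cfg


@pytest.fixture(scope="session")
def full_cohort():
    """Default-sized cohort mirroring the emulated study's shape."""
    cohort, truth = generate_fixture(FixtureConfig(seed=42))
    return cohort, truth


@pytest.fixture(scope="session")
def trained_mt(small_cohort):
    """A small LSTM-encoder module trained on the times module."""
    cohort, _, _ = small_cohort
    values, mask, specs = cohort.module_slice("T")
    cfg = HivaeConfig(variant="MT", epochs=40, seed=3)
    model, enc = fit_module(values, mask, specs, cfg)
    return model, enc, values, mask
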