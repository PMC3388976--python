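import numpy as np
import pytest

from instars.inference import build_anchors, select_instar_number
from instars.synthgen import default_config, sample_population


@pytest.fixture(scope="session")
def config():
    return default_config()


@pytest.fixture(scope="session")
def default_table(config):
    """The default synthetic population at the default seed."""
    return sample_population(config, seed=config.seed)


@pytest.fixture(scope="session")
def default_widths(default_table):
    return default_table.head_widths()


@pytest.fixture(scope="session")
def default_selection(default_table, default_widths):
    """BIC sweep (K=1..6, anchored) on the default population; reused widely."""
    anchors = build_anchors(default_table)
    return select_instar_number(default_widths, k_max=6, anchors=anchors)


@pytest.fixture(scope="session")
def default_mixture(default_selection):
    return default_selection.model


@pytest.fixture(scope="session")
def unimodal_widths():
    """500 draws from a single normal (0.15, 0.006) — one instar by construction."""
    rng = np.random.default_rng(42)
    return rng.normal(0.15, 0.006, size=500)
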