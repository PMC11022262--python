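import logging

import numpy as np
import pytest

from eipcea.economics import ModelContext
from eipcea.synthesis import SynthesisConfig
from eipcea.synthetic import default_inputs, default_life_table, default_parameter_fixture

# capping warnings are expected in the PSA tails; keep test output readable
logging.getLogger("eipcea.markov").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def table():
    return default_parameter_fixture()


@pytest.fixture(scope="session")
def life_table():
    return default_life_table()


@pytest.fixture(scope="session")
def ctx(life_table):
    return ModelContext(life_table=life_table)


@pytest.fixture(scope="session")
def bundle():
    """The frozen synthetic study bundle (parameters, life table, trials, IPD)."""
    return default_inputs()


def fast_synthesis_config(**kwargs) -> SynthesisConfig:
    """Reduced sampler settings for unit tests (a few seconds per fit)."""
    defaults = dict(iterations=6_000, burn_in=1_500, seed=11)
    defaults.update(kwargs)
    return SynthesisConfig(**defaults)
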