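import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, max_examples=50)
settings.load_profile("deterministic")

import bidimr


@pytest.fixture(scope="session")
def independent_cohort():
    """One mid-size cohort from the INDEPENDENT scenario (all six effects, no causal path)."""
    params = bidimr.default_presets("INDEPENDENT", n=50_000, seed=11)
    return bidimr.simulate_cohort(params)


@pytest.fixture(scope="session")
def t2d_instruments():
    return bidimr.packaged_instruments("T2D")


@pytest.fixture(scope="session")
def vitd_instruments():
    return bidimr.packaged_instruments("VITD")


@pytest.fixture()
def tiny_cohort():
    """A 200-sample null cohort for cheap structural tests."""
    params = bidimr.default_presets("NULL", n=200, seed=5)
    return bidimr.simulate_cohort(params)
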