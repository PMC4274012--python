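import numpy as np
import pytest
from hypothesis import settings

from memsim import presets
from memsim.gene_model import CellCycleParams, GeneParams

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def cycle():
    return presets.CYCLE


@pytest.fixture(scope="session")
def stable_pair():
    return presets.stable_pair()


@pytest.fixture(scope="session")
def unstable_pair():
    return presets.unstable_pair()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_gene(**kw) -> GeneParams:
    """A gene with all rates zero unless overridden."""
    base = dict(k_open=0.0, k_close=0.0, k_burst=0.0, burst_size_mean=1.0,
                k_tl=0.0, delta_m=0.0, delta_p=0.0, name="g")
    base.update(kw)
    return GeneParams(**base)


@pytest.fixture(scope="session")
def no_division():
    """A cycle far longer than any test horizon (effectively no divisions)."""
    return CellCycleParams(T_div=1e12, cv_div=0.0)
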