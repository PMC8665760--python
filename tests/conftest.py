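import numpy as np
import pytest

from famscape.align import AlignParams, calibrate_evalue
from famscape.synth import standard_benchmark


@pytest.fixture(scope="session")
def params():
    return AlignParams()


@pytest.fixture(scope="session")
def ka200(params):
    """Gumbel calibration for 200-residue pairwise comparisons, shared."""
    return calibrate_evalue(params, 200, n_shuffles=500, rng_seed=11)


@pytest.fixture(scope="session")
def standard_bench():
    """The canonical 8-family discovery benchmark (fixed seed)."""
    return standard_benchmark(rng_seed=1)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
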