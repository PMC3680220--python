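import numpy as np
import pytest

from mirconsensus import gen_reference
from mirconsensus.synthetic import DEFAULT_ADAPTER

ADAPTER = DEFAULT_ADAPTER


@pytest.fixture(scope="session")
def reference():
    """Small random miRNA reference shared across tests."""
    return gen_reference(20, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_seq(rng, n):
    return "".join("ACGT"[b] for b in rng.integers(0, 4, size=n))
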