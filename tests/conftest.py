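import numpy as np
import pytest

import lipidqtl as lq


@pytest.fixture
def tiny_lengths():
    return {"c1": 300000, "c2": 200000}


@pytest.fixture
def tiny_map(tiny_lengths):
    return lq.build_parental_map(600, tiny_lengths, seed=11)


@pytest.fixture
def tiny_gmap(tiny_lengths):
    return lq.GeneticMap.uniform(tiny_lengths)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
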