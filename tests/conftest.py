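import numpy as np
import pytest

from phylofuse.cli import _random_fixture


@pytest.fixture
def rng():
    return np.random.default_rng(20130409)


@pytest.fixture
def random_fixture():
    """Factory: random tree + compressed patterns + valid GTR+I+Gamma params."""
    def make(rng, n_taxa, n_patterns, with_ambiguity=False):
        return _random_fixture(rng, n_taxa, n_patterns,
                               with_ambiguity=with_ambiguity)
    return make
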