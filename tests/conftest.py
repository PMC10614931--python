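import numpy as np
import pytest

import twasvc as tv


@pytest.fixture(scope="session")
def small_panel():
    """300-variant identity-LD panel for 500 individuals, standardized."""
    return tv.simulate_genotypes(500, tv.LdSpec.identity(300), seed=101,
                                 standardize=True)


@pytest.fixture(scope="session")
def dense_weights(small_panel):
    return tv.simulate_mediator_weights(300, 300, seed=102,
                                        variant_ids=small_panel.variant_ids)


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
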