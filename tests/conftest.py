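import numpy as np
import pytest

from gammamaxt import SimConfig, simulate_null


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture
def make_null():
    """Factory for small null datasets with a fixed per-call seed."""

    def _make(trait_type="binary", n_snps=12, n_ind=80, missing_rate=0.0, seed=0):
        cfg = SimConfig(
            n_snps=n_snps,
            n_individuals=n_ind,
            trait_type=trait_type,
            missing_rate=missing_rate,
        )
        return simulate_null(cfg, np.random.default_rng(seed))

    return _make
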