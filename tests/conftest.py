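import numpy as np
import pytest

import ratesmooth as rs


@pytest.fixture
def cherry():
    return rs.parse_newick("(A:1,B:1);")


@pytest.fixture
def three_tip():
    return rs.parse_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def tree_factory():
    """Reproducible pure-birth trees of a requested size."""

    def make(n_tips: int, seed: int = 0):
        return rs.simulate_pure_birth_tree(n_tips, seed)

    return make


def full_log_rates(rates: rs.RateState) -> np.ndarray:
    """Non-root log-rates followed by the root log-rate, as one vector."""
    return np.concatenate([rates.s, [rates.s0]])


def random_rate_state(tree, rng, scale=1.0) -> rs.RateState:
    return rs.RateState(rng.normal(0.0, scale, tree.n + tree.m - 1),
                        float(rng.normal(0.0, scale)))
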