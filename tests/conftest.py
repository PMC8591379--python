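import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import allomvox as av

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

THREE_TIP_NEWICK = "((A:1,B:1):1,C:2);"


@pytest.fixture
def three_tip_tree() -> av.Phylogeny:
    return av.parse_newick(THREE_TIP_NEWICK)[0]


@pytest.fixture
def star_tree() -> av.Phylogeny:
    return av.parse_newick("(A:1,B:1,C:1,D:1);")[0]


@pytest.fixture
def random_tree():
    """Factory for reproducible Yule trees of a given size."""
    from allomvox.simulate import simulate_tree

    def make(n: int, seed: int = 0) -> av.Phylogeny:
        return simulate_tree(n, seed)

    return make


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20220103)
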