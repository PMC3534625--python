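import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import cogevo as cg

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def three_leaf_tree():
    return cg.read_newick("((A:1,B:1):0.5,C:2)R;")


@pytest.fixture
def five_leaf_tree():
    return cg.read_newick("(((A,B),C),(D,E));")


@pytest.fixture
def rng():
    return np.random.default_rng(20240801)


def random_tree(rng, n_leaves):
    """Random rooted tree (possibly multifurcating) with n_leaves leaves."""
    names = iter(f"t{i}" for i in range(n_leaves))

    def build(budget):
        if budget == 1:
            return next(names)
        k = int(rng.integers(2, min(3, budget) + 1))
        cuts = sorted(rng.choice(np.arange(1, budget), size=k - 1, replace=False))
        parts = np.diff([0, *cuts, budget])
        return "(" + ",".join(build(int(p)) for p in parts) + ")"

    return cg.read_newick(build(n_leaves) + ";")


def random_model(rng, n_branches, two_cat=False, condition=False):
    gain = rng.uniform(0.05, 0.95, n_branches)
    loss = rng.uniform(0.05, 0.95, n_branches)
    if two_cat:
        return cg.GainLossModel(
            gain,
            loss,
            multipliers=np.array([1.0, float(rng.uniform(1.5, 4.0))]),
            weights=np.array([0.6, 0.4]),
            condition_on_observed=condition,
        )
    return cg.GainLossModel(gain, loss, condition_on_observed=condition)
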