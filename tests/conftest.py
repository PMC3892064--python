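import numpy as np
import pytest

import lucaml as lm


@pytest.fixture
def four_leaf_tree() -> lm.PhylogeneticTree:
    return lm.parse_newick("((A:0.3,B:0.7):0.2,(C:0.4,D:0.1):0.6);")


@pytest.fixture
def five_leaf_tree() -> lm.PhylogeneticTree:
    """Five extant species, three internal nodes plus the root — the shape
    of the worked likelihood example with phyletic vector (0,1,1,m,1)."""
    return lm.parse_newick(
        "(((sp1:0.35,sp2:0.35):0.35,sp3:0.35):0.35,(sp4:0.35,sp5:0.35):0.35);"
    )


@pytest.fixture
def three_state_prior() -> lm.RootPrior:
    return lm.make_root_prior("three-state")


@pytest.fixture
def binary_prior() -> lm.RootPrior:
    return lm.make_root_prior("binary")


def random_instance(rng: np.random.Generator, family: str):
    """A random small tree, rates and phyletic vector for oracle checks."""
    n_leaves = int(rng.integers(2, 7))
    tree = lm.random_tree(n_leaves, rng, min_branch=0.01, max_branch=2.0)
    if family == "binary":
        model_id = rng.choice(["B1", "B2"])
        k = 2
    else:
        model_id = rng.choice(["M1", "M2"])
        k = 3
    names = lm.models.MODEL_PARAM_NAMES[model_id]
    params = lm.RateParameters(
        model_id, {n: float(rng.uniform(0.05, 5.0)) for n in names}
    )
    v = rng.integers(0, k, size=n_leaves)
    prior = lm.make_root_prior("binary" if k == 2 else "three-state")
    return tree, params, v, prior
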