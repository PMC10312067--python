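import numpy as np
import pandas as pd
import pytest

from treetmle.core_data import MixtureDataset
from treetmle.super_learner import LearnerSpec
from treetmle.tmle import RunSettings


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def lean_library():
    """Mean + linear only: fast and well-specified for the simulated
    additive scenarios used throughout the suite."""
    return [LearnerSpec.make("mean", "mean"), LearnerSpec.make("linear", "linear")]


@pytest.fixture
def lean_settings(lean_library):
    def make(seed: int, **overrides) -> RunSettings:
        kwargs = dict(
            V=5,
            seed=seed,
            w_library=lean_library,
            tree_max_depths=(1, 2),
            tree_min_leaf_fracs=(0.05,),
            run_components=False,
        )
        kwargs.update(overrides)
        return RunSettings(**kwargs)

    return make


def make_dataset(
    n: int = 100,
    p: int = 2,
    q: int = 1,
    seed: int = 0,
    y=None,
) -> MixtureDataset:
    rng = np.random.default_rng(seed)
    A = pd.DataFrame(
        rng.uniform(0, 1, size=(n, p)), columns=[f"x{j + 1}" for j in range(p)]
    )
    W = pd.DataFrame(
        rng.standard_normal((n, q)), columns=[f"w{k + 1}" for k in range(q)]
    )
    if y is None:
        y = rng.standard_normal(n)
    return MixtureDataset(exposures=A, covariates=W, outcome=np.asarray(y))


@pytest.fixture
def small_dataset():
    return make_dataset(n=100, p=2, q=1, seed=0)
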