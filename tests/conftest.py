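import warnings

import numpy as np
import pytest

from seqsimrank.data import TaskSpec, build_ranking_dataset
from seqsimrank.synth import (
    HeteroBenchSpec,
    HomoBenchSpec,
    generate_hetero_benchmark,
    generate_homo_benchmark,
)

# scikit-learn 1.9 deprecation chatter (SVC probability) is not ours to fix
warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def homo_bench():
    """The reference clustered-family benchmark: 20 families x 10 members,
    dim 16, noise 0.5, seed 1."""
    corpus, labels, truth = generate_homo_benchmark(HomoBenchSpec(seed=1))
    return corpus, labels, truth


@pytest.fixture(scope="session")
def homo_dataset(homo_bench):
    corpus, labels, _ = homo_bench
    task = TaskSpec("homogeneous", corpus)
    return build_ranking_dataset(task, labels, seed=1)


@pytest.fixture(scope="session")
def homo_matrix_dataset():
    """Token-matrix variant for the interaction matchers (L=8, D=8)."""
    corpus, labels, _ = generate_homo_benchmark(
        HomoBenchSpec(dim=8, noise_sd=0.3, seed=1, layout="matrix", tokens=8)
    )
    task = TaskSpec("homogeneous", corpus)
    return build_ranking_dataset(task, labels, seed=1)


@pytest.fixture(scope="session")
def hetero_bench():
    """The reference bipartite benchmark: 50x50, density 0.1, noise 0.3, seed 1."""
    return generate_hetero_benchmark(HeteroBenchSpec(seed=1))


@pytest.fixture(scope="session")
def hetero_dataset(hetero_bench):
    ca, cb, labels, _ = hetero_bench
    task = TaskSpec("heterogeneous", ca, cb)
    return build_ranking_dataset(task, labels, seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
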