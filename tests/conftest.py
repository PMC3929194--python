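import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from coexnet.network import AdjacencyMatrix
from coexnet.preprocess import ExpressionMatrix
from coexnet.simulate import reference_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(20140130)


@pytest.fixture
def small_expression(rng):
    values = rng.normal(size=(5, 50))
    return ExpressionMatrix(
        gene_ids=[f"g{i}" for i in range(5)],
        sample_ids=[f"s{j}" for j in range(50)],
        values=values,
    )


@pytest.fixture
def cohort():
    return reference_cohort()


def binary_adjacency(a):
    return AdjacencyMatrix(
        gene_ids=[f"g{i}" for i in range(a.shape[0])], a=a, mode="hard",
        threshold_tau=0.7,
    )


def weighted_adjacency(a):
    return AdjacencyMatrix(
        gene_ids=[f"g{i}" for i in range(a.shape[0])], a=a, mode="soft",
        power_beta=7.0,
    )
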