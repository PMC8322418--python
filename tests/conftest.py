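import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from kboost import ExpressionMatrix, SimulationSpec, TFIndex, simulate_expression, simulate_network


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_expression(rng):
    """8 genes x 12 samples of random expression, first 3 genes are TFs."""
    values = rng.standard_normal((8, 12))
    return ExpressionMatrix(
        values=values,
        gene_ids=tuple(f"G{i}" for i in range(8)),
        sample_ids=tuple(f"S{i}" for i in range(12)),
    )


@pytest.fixture
def small_tfs():
    return TFIndex((0, 1, 2))


@pytest.fixture
def tiny_benchmark():
    """A 12-gene, 4-TF simulated benchmark with its generating gold standard."""
    spec = SimulationSpec(
        n_genes=12, n_tfs=4, avg_outdegree=2.5, n_samples=40, noise_sd=0.2, seed=11
    )
    gold = simulate_network(spec)
    X = simulate_expression(gold, spec)
    return spec, gold, X
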