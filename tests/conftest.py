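import numpy as np
import pytest

from modnet import (
    ExpressionMatrix,
    GibbsConfig,
    NormalGammaPrior,
    TwoWayClustering,
    generate,
    run_gibbs,
)


@pytest.fixture(scope="session")
def prior():
    return NormalGammaPrior()


@pytest.fixture(scope="session")
def benchmark_data():
    """Default synthetic benchmark instance (planted modules and regulators)."""
    return generate(seed=11)


@pytest.fixture(scope="session")
def small_matrix():
    """12 genes x 10 samples, 3 planted modules, no missing values."""
    rng = np.random.default_rng(5)
    means = np.array([[1.5] * 5 + [-1.5] * 5, [-1.0] * 5 + [1.0] * 5, [0.0] * 10])
    rows, genes = [], []
    for m in range(3):
        for i in range(4):
            genes.append(f"m{m}g{i}")
            rows.append(means[m] + rng.normal(0, 0.4, 10))
    samples = [f"c{j}" for j in range(10)]
    return ExpressionMatrix(genes, samples, np.array(rows))


@pytest.fixture(scope="session")
def random_clustering(small_matrix):
    """Arbitrary valid 3-module two-way clustering of small_matrix."""
    rng = np.random.default_rng(17)
    module_of = {g: int(rng.integers(0, 3)) for g in small_matrix.gene_ids}
    while len(set(module_of.values())) < 3:  # keep all three modules occupied
        module_of[small_matrix.gene_ids[0]] = 2
    parts = {}
    for k in range(3):
        parts[k] = {s: int(rng.integers(0, 2)) for s in small_matrix.sample_ids}
    return TwoWayClustering(module_of, parts)


@pytest.fixture(scope="session")
def quick_gibbs_config():
    return GibbsConfig(num_sweeps=30, burn_in=5, greedy_sweeps=5, seed=3)


@pytest.fixture(scope="session")
def benchmark_run(benchmark_data, quick_gibbs_config):
    matrix, _, _ = benchmark_data
    return run_gibbs(matrix, config=quick_gibbs_config)
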