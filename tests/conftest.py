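import numpy as np
import pytest

from uniss.simdata import (
    GenotypeMatrix,
    PhenotypeTable,
    SimulationConfig,
    simulate_dataset,
)


@pytest.fixture(scope="session")
def tiny_sim():
    """Small but structured dataset: 120 samples, 150 variants, 4 traits."""
    config = SimulationConfig(
        n=120, p=150, q=4, trait_split=(2, 2), n_regions=3, rho_x=0.6, seed=101
    )
    X, Y, truth = simulate_dataset(config)
    return config, X, Y, truth


@pytest.fixture(scope="session")
def causal_toy():
    """One strong causal variant (beta=3 on the quantitative trait) among 50."""
    rng = np.random.default_rng(7)
    n, p = 200, 50
    G = rng.binomial(2, 0.3, size=(n, p)).astype(np.int8)
    y_quant = 3.0 * G[:, 0] + rng.standard_normal(n)
    y_bin = (y_quant > np.median(y_quant)).astype(float)
    X = GenotypeMatrix(
        values=G,
        variant_ids=[f"snp_{j + 1}" for j in range(p)],
        sample_ids=[f"sample_{i + 1}" for i in range(n)],
        maf=G.mean(axis=0) / 2.0,
    )
    Y = PhenotypeTable(
        values=np.column_stack([y_quant, y_bin]),
        trait_types=["quantitative", "binary"],
        trait_ids=["trait_q", "trait_b"],
        sample_ids=list(X.sample_ids),
    )
    return X, Y
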