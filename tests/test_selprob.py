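"""Bootstrap selection probabilities: sampling law, bookkeeping against a
brute-force loop, and penalty choice."""

import numpy as np
import pytest

from uniss.regularization import ElasticNetSpec, fit_support, lambda_path
from uniss.selprob import (
    _seed_sequence,
    bootstrap_sample,
    choose_lambda,
    selection_probabilities,
)


def test_bootstrap_sample_uniform_with_replacement():
    rng = np.random.default_rng(0)
    n = 400
    counts = np.zeros(n)
    draws = 10_000
    for _ in range(draws):
        idx = bootstrap_sample(n, rng)
        assert idx.shape == (n,) and idx.min() >= 0 and idx.max() < n
        counts[idx[0]] += 1  # first element of each draw is one uniform sample
    se = np.sqrt((1 / n) * (1 - 1 / n) / draws)
    assert np.all(np.abs(counts / draws - 1 / n) < 5 * se)


def test_bootstrap_unique_fraction_near_632():
    """Classical bootstrap property: ~1 - 1/e of the sample is unique."""
    rng = np.random.default_rng(1)
    n = 2_000
    fracs = [len(np.unique(bootstrap_sample(n, rng))) / n for _ in range(50)]
    assert abs(np.mean(fracs) - (1 - np.exp(-1))) < 0.01


def test_bootstrap_sample_rejects_invalid_n():
    with pytest.raises(ValueError):
        bootstrap_sample(0, np.random.default_rng(0))


def test_entries_are_multiples_of_one_over_B(causal_toy):
    X, Y = causal_toy
    for B in (1, 7):
        S = selection_probabilities(X, Y, B=B, seed=3)
        scaled = S.values * B
        assert np.allclose(scaled, np.round(scaled))
        assert S.values.min() >= 0.0 and S.values.max() <= 1.0
        if B == 1:
            assert set(np.unique(S.values)) <= {0.0, 1.0}


def test_huge_lambda_gives_all_zero_matrix(causal_toy):
    X, Y = causal_toy
    S = selection_probabilities(X, Y, B=5, seed=4, lambda_per_trait=[1e6, 1e6])
    assert not S.values.any()


def test_matches_brute_force_fit_loop(causal_toy):
    """The pipeline's shared-resample bookkeeping reproduces a plain loop of
    independent public-API fits on the same index draws."""
    X, Y = causal_toy
    B, seed = 12, 5
    spec = ElasticNetSpec()
    S = selection_probabilities(X, Y, spec=spec, B=B, seed=seed)

    counts = np.zeros_like(S.values)
    n = X.n_samples
    for l in range(B):
        rng_l = np.random.default_rng(_seed_sequence(seed, l))
        idx = bootstrap_sample(n, rng_l)
        for k, family in enumerate(["gaussian", "binomial"]):
            res = fit_support(
                X.values[idx], Y.values[idx, k], family=family,
                lam=float(S.lambda_per_trait[k]), spec=spec,
            )
            counts[:, k] += res.support
    assert np.array_equal(S.values, counts / B)


def test_causal_variant_has_high_selection_probability(causal_toy):
    X, Y = causal_toy
    S = selection_probabilities(X, Y, B=50, seed=6)
    assert S.values[0, 0] >= 0.9  # quantitative trait
    assert S.values[0, 1] >= 0.9  # binary trait
    assert np.median(S.values[1:, 0]) <= 0.1
    # logistic supports run denser at the median penalty; null variants must
    # still sit far below the causal one
    assert np.median(S.values[1:, 1]) <= 0.3
    assert S.values[1:, 1].max() < S.values[0, 1]


def test_seed_reproducibility_and_B_stability(causal_toy):
    X, Y = causal_toy
    S1 = selection_probabilities(X, Y, B=25, seed=8)
    S2 = selection_probabilities(X, Y, B=25, seed=8)
    assert np.array_equal(S1.values, S2.values)
    S3 = selection_probabilities(X, Y, B=50, seed=8)
    assert np.abs(S3.values - S1.values).max() <= 0.25


def test_choose_lambda_is_lower_median_of_path(causal_toy):
    X, Y = causal_toy
    y = Y.values[:, 0]
    spec = ElasticNetSpec()
    path = lambda_path(X, y, "gaussian", spec)
    assert choose_lambda(X.values, y, "gaussian", spec) == path[49]  # rank 50 of 100
    spec3 = ElasticNetSpec(n_lambda=3)
    path3 = lambda_path(X, y, "gaussian", spec3)
    assert choose_lambda(X.values, y, "gaussian", spec3) == path3[1]  # odd-length median
    assert choose_lambda(X.values, y, "gaussian", spec, quantile=0.9) == path[89]
    with pytest.raises(ValueError):
        choose_lambda(X.values, y, "gaussian", spec, quantile=0.0)


def test_selection_robust_to_lambda_quantile():
    """Moving the penalty from the path median towards smaller values leaves
    top-k recovery unchanged, and perturbs the ranking no more than
    re-drawing the bootstrap at a fixed penalty does."""
    from scipy.stats import spearmanr

    from uniss.evaluation import top_k_selection, true_positive_rate
    from uniss.scoring import unified_scores
    from uniss.simdata import SimulationConfig, simulate_dataset

    cfg = SimulationConfig(n=200, p=500, q=4, trait_split=(2, 2), n_regions=4,
                           rho_x=0.6, seed=77)
    X, Y, truth = simulate_dataset(cfg)
    res_med = unified_scores(selection_probabilities(X, Y, B=50, seed=9, lambda_quantile=0.5))
    res_low = unified_scores(selection_probabilities(X, Y, B=50, seed=9, lambda_quantile=0.6))
    res_reseed = unified_scores(selection_probabilities(X, Y, B=50, seed=10, lambda_quantile=0.5))

    tpr_med = true_positive_rate(top_k_selection(res_med, 40)[0], truth)
    tpr_low = true_positive_rate(top_k_selection(res_low, 40)[0], truth)
    assert abs(tpr_med - tpr_low) <= 0.1
    rho_lambda = spearmanr(res_med.pi, res_low.pi).statistic
    rho_reseed = spearmanr(res_med.pi, res_reseed.pi).statistic
    assert rho_lambda > rho_reseed - 0.05


def test_redraw_handles_degenerate_binary_resamples():
    """A rare binary trait makes some resamples constant; they are redrawn
    and the result stays a valid probability matrix."""
    from uniss.simdata import GenotypeMatrix, PhenotypeTable

    rng = np.random.default_rng(10)
    n, p = 40, 10
    G = rng.binomial(2, 0.4, size=(n, p)).astype(np.int8)
    yb = np.zeros(n)
    yb[:3] = 1.0  # resamples missing all three cases are degenerate
    X = GenotypeMatrix(G, [f"v{j}" for j in range(p)], [f"s{i}" for i in range(n)],
                       G.mean(0) / 2)
    Y = PhenotypeTable(yb[:, None], ["binary"], ["rare"], list(X.sample_ids))
    S = selection_probabilities(X, Y, B=20, seed=11, lambda_per_trait=[0.05])
    assert S.values.shape == (p, 1)
    assert S.values.min() >= 0 and S.values.max() <= 1


def test_null_selection_probabilities_exchangeable_across_variants():
    """With phenotypes permuted (global null), selection probabilities of
    two disjoint variant groups at a common MAF are indistinguishable
    (Kolmogorov-Smirnov)."""
    from scipy import stats

    from uniss.simdata import GenotypeMatrix, PhenotypeTable, SimulationConfig, generate_genotypes

    cfg = SimulationConfig(n=100, p=200, q=2, trait_split=(1, 1), n_regions=0,
                           rho_x=0.0, maf_range=(0.3, 0.3), seed=31)
    X = generate_genotypes(cfg)
    rng = np.random.default_rng(32)
    yq = rng.standard_normal(100)
    yb = (np.arange(100) % 2).astype(float)
    rng.shuffle(yb)
    Y = PhenotypeTable(np.column_stack([yq, yb]), ["quantitative", "binary"],
                       ["q", "b"], list(X.sample_ids))
    pvals = []
    for seed in (33, 34, 35):
        S = selection_probabilities(X, Y, B=30, seed=seed)
        for k in range(2):
            col = S.values[:, k]
            pvals.append(stats.ks_2samp(col[:100], col[100:]).pvalue)
    assert np.mean(np.array(pvals) > 0.01) >= 0.95
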