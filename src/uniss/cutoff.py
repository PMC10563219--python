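"""Permutation null and the theta-calibrated selection cut-off.

Unified scores rank variants but do not by themselves select a set.  The
cut-off is calibrated by rerunning the whole scoring pipeline on data with
the phenotype rows jointly permuted (genotypes untouched), which breaks
every genotype-phenotype association while preserving trait-trait
correlation.  Averaging the theta-th largest permuted-data score over T
permutations gives ``c(theta)``; selecting variants whose observed score
strictly exceeds it yields around ``theta`` expected false selections, so
theta plays the role a significance level does in testing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from uniss.regularization import ElasticNetSpec
from uniss.scoring import EtaRule, UnifiedScoreResult, unified_scores
from uniss.selprob import SeedLike, _seed_sequence, selection_probabilities
from uniss.simdata import PhenotypeTable

__all__ = ["PermutationNull", "permute_phenotypes", "permutation_cutoff", "select_variants"]

_STREAM_PERMUTATION = 101
_STREAM_PERM_BOOTSTRAP = 102


@dataclass
class PermutationNull:
    """Top permuted-data scores per permutation and the derived cut-offs."""

    T: int
    theta_values: list[int]
    per_permutation_top_scores: np.ndarray  # T x max(theta)
    cutoffs: dict[int, float]
    seed: int | None

    def __post_init__(self) -> None:
        tops = self.per_permutation_top_scores
        if tops.shape[0] != self.T:
            raise ValueError("top-score matrix row count must equal T")
        if np.any(np.diff(tops, axis=1) > 1e-12):
            raise ValueError("per-permutation top scores must be non-increasing")


def permute_phenotypes(Y: PhenotypeTable, rng: np.random.Generator) -> PhenotypeTable:
    """Apply one row permutation jointly to all traits.

    Rows move together, so each trait column is a rearrangement of itself
    and all trait-trait correlations are preserved exactly; only the pairing
    with genotype rows is destroyed.
    """
    perm = rng.permutation(Y.n_samples)
    return PhenotypeTable(
        values=Y.values[perm, :],
        trait_types=list(Y.trait_types),
        trait_ids=list(Y.trait_ids),
        sample_ids=list(Y.sample_ids),
        levels=dict(Y.levels),
    )


def permutation_cutoff(
    X,
    Y: PhenotypeTable,
    covariates: Optional[np.ndarray] = None,
    spec: ElasticNetSpec = ElasticNetSpec(),
    B: int = 100,
    T: int = 100,
    theta_values: Sequence[int] = (5, 10, 20, 30, 40, 50),
    lambda_per_trait: Optional[Sequence[float]] = None,
    seed: SeedLike = 0,
    eta_rule: EtaRule = "min",
) -> PermutationNull:
    """Score T phenotype-permuted datasets and average order statistics.

    The permuted analyses reuse the per-trait penalties of the observed
    analysis (``lambda_per_trait``, required): the null describes the score
    distribution at the penalty actually used, not at penalties re-tuned to
    noise.  Covariates are not permuted; they stay aligned with the genotype
    rows, so the null is "no genotype-phenotype association given covariates".

    Permutation t uses its own substream for the row shuffle and a separate
    substream family for its bootstrap replicates, making every permuted
    analysis reproducible in isolation.
    """
    if T < 1:
        raise ValueError("T must be at least 1")
    if lambda_per_trait is None:
        raise ValueError(
            "lambda_per_trait is required: the null must reuse the observed-data penalties"
        )
    theta_values = [int(t) for t in theta_values]
    p = X.values.shape[1] if hasattr(X, "values") else np.asarray(X).shape[1]
    if any(t < 1 or t > p for t in theta_values):
        raise ValueError("every theta must lie in {1, ..., p}")
    max_theta = max(theta_values)

    tops = np.empty((T, max_theta))
    for t in range(T):
        rng_t = np.random.default_rng(_seed_sequence(seed, _STREAM_PERMUTATION, t))
        Yp = permute_phenotypes(Y, rng_t)
        S = selection_probabilities(
            X, Yp, covariates, spec, B,
            seed=_seed_sequence(seed, _STREAM_PERM_BOOTSTRAP, t),
            lambda_per_trait=lambda_per_trait,
        )
        result = unified_scores(S, eta_rule)
        pi_sorted = np.sort(result.pi)[::-1]
        tops[t] = pi_sorted[:max_theta]

    cutoffs = {theta: float(tops[:, theta - 1].mean()) for theta in theta_values}
    return PermutationNull(
        T=T,
        theta_values=theta_values,
        per_permutation_top_scores=tops,
        cutoffs=cutoffs,
        seed=seed if isinstance(seed, int) else None,
    )


def select_variants(result: UnifiedScoreResult, c: float) -> np.ndarray:
    """Variant indices whose unified score strictly exceeds the cut-off,
    ordered by descending score (ties by ascending index)."""
    return result.order[result.pi[result.order] > c]


def write_cutoffs(path, null: PermutationNull, result: Optional[UnifiedScoreResult] = None) -> None:
    """TSV: theta, cut-off and (if scores are given) the selected count."""
    with open(path, "w") as fh:
        fh.write(f"#T\t{null.T}\n")
        header = "theta\tcutoff"
        if result is not None:
            header += "\tn_selected"
        fh.write(header + "\n")
        for theta in null.theta_values:
            c = null.cutoffs[theta]
            line = f"{theta}\t{c:.10g}"
            if result is not None:
                line += f"\t{len(select_variants(result, c))}"
            fh.write(line + "\n")
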