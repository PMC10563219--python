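"""Bootstrap selection probabilities per variant and trait.

For each trait, the data are resampled with replacement B times and an
elastic net is fitted at a fixed, trait-specific penalty; the selection
probability ``s[j, k]`` is the fraction of resamples in which variant j's
coefficient is nonzero for trait k.  One resample (index multiset) per
bootstrap replicate is shared by all traits, so trait-wise probabilities
are comparable under identical resampling noise.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np

from uniss.regularization import (
    ElasticNetSpec,
    Family,
    _fit_standardized,
    lambda_path,
    standardize_columns,
)
from uniss.simdata import GenotypeMatrix, PhenotypeTable

__all__ = [
    "SelectionProbabilityMatrix",
    "bootstrap_sample",
    "choose_lambda",
    "selection_probabilities",
    "write_selection_probabilities",
]

logger = logging.getLogger(__name__)

SeedLike = Union[int, np.random.SeedSequence]


def _seed_sequence(seed: SeedLike, *key: int) -> np.random.SeedSequence:
    if isinstance(seed, np.random.SeedSequence):
        base_entropy, base_key = seed.entropy, tuple(seed.spawn_key)
    else:
        base_entropy, base_key = int(seed), ()
    return np.random.SeedSequence(entropy=base_entropy, spawn_key=base_key + key)


@dataclass
class SelectionProbabilityMatrix:
    """p x q matrix of bootstrap nonzero frequencies, with provenance."""

    values: np.ndarray
    lambda_per_trait: np.ndarray
    B: int
    alpha: float
    trait_ids: list[str]
    variant_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        p, q = self.values.shape
        if len(self.variant_ids) != p or len(self.trait_ids) != q:
            raise ValueError("id lists do not match matrix dimensions")
        if len(self.lambda_per_trait) != q:
            raise ValueError("lambda_per_trait length must equal trait count")
        if self.values.min(initial=0.0) < 0.0 or self.values.max(initial=0.0) > 1.0:
            raise ValueError("selection probabilities must lie in [0, 1]")


def bootstrap_sample(n: int, rng: np.random.Generator) -> np.ndarray:
    """One bootstrap index multiset: n i.i.d. uniform draws with replacement."""
    if n < 1:
        raise ValueError("n must be positive")
    return rng.integers(0, n, size=n)


def choose_lambda(
    X,
    y: np.ndarray,
    family: Family = "gaussian",
    spec: ElasticNetSpec = ElasticNetSpec(),
    covariates: Optional[np.ndarray] = None,
    quantile: float = 0.5,
) -> float:
    """Pick the penalty at a path quantile; the default is the lower median.

    On the default 100-value descending path the lower median is the 50th
    largest value.  A large penalty yields supports too sparse to compare
    across bootstraps, a tiny one too dense; the median is a robust middle
    ground, and rankings are empirically stable from the median downwards.
    """
    if not (0.0 < quantile <= 1.0):
        raise ValueError("quantile must lie in (0, 1]")
    path = lambda_path(X, y, family, spec, covariates)
    rank = max(1, math.ceil(quantile * spec.n_lambda))  # 1-based, descending
    return float(path[rank - 1])


def _resample_is_degenerate(Yv: np.ndarray, binary_cols: np.ndarray, idx: np.ndarray) -> bool:
    for k in np.flatnonzero(binary_cols):
        col = Yv[idx, k]
        if col.min() == col.max():
            return True
    return False


def selection_probabilities(
    X,
    Y: PhenotypeTable,
    covariates: Optional[np.ndarray] = None,
    spec: ElasticNetSpec = ElasticNetSpec(),
    B: int = 100,
    seed: SeedLike = 0,
    lambda_per_trait: Optional[Sequence[float]] = None,
    lambda_quantile: float = 0.5,
) -> SelectionProbabilityMatrix:
    """Bootstrap nonzero frequencies for every (variant, trait) pair.

    Per-trait penalties default to the median of each trait's own 100-value
    path computed on the full data; pass ``lambda_per_trait`` to reuse
    penalties from a previous run (as the permutation null must).

    Bootstrap replicates use deterministic per-replicate substreams of
    ``seed``, so results do not depend on execution order.  A replicate in
    which any binary trait becomes constant is redrawn from the same
    substream; more than ``B`` total redraws abort.
    """
    if B < 1:
        raise ValueError("B must be at least 1")
    Xm = X.values if isinstance(X, GenotypeMatrix) else np.asarray(X, dtype=np.float64)
    n, p = Xm.shape
    if Y.n_samples != n:
        raise ValueError("genotype and phenotype sample counts differ")
    q = Y.n_traits
    families: list[Family] = [
        "binomial" if t == "binary" else "gaussian" for t in Y.trait_types
    ]

    Xc = None
    n_cov = 0
    if covariates is not None:
        Xc = np.asarray(covariates, dtype=np.float64)
        if Xc.ndim == 1:
            Xc = Xc[:, None]
        n_cov = Xc.shape[1]

    if lambda_per_trait is None:
        lambda_per_trait = [
            choose_lambda(Xm, Y.values[:, k], families[k], spec, Xc, lambda_quantile)
            for k in range(q)
        ]
    lambda_per_trait = np.asarray(lambda_per_trait, dtype=np.float64)
    if len(lambda_per_trait) != q:
        raise ValueError("lambda_per_trait length must equal trait count")

    binary_cols = Y.is_binary()
    pf = np.concatenate([np.zeros(n_cov), np.ones(p)])
    counts = np.zeros((p, q), dtype=np.int64)
    redraws = 0
    for l in range(B):
        rng_l = np.random.default_rng(_seed_sequence(seed, l))
        idx = bootstrap_sample(n, rng_l)
        while _resample_is_degenerate(Y.values, binary_cols, idx):
            redraws += 1
            logger.info("bootstrap replicate %d redrawn (constant binary trait)", l)
            if redraws > B:
                raise RuntimeError(
                    "more than B bootstrap replicates produced a constant binary trait"
                )
            idx = bootstrap_sample(n, rng_l)

        Xs, _, _ = standardize_columns(Xm[idx])
        if Xc is not None:
            Xcs, _, _ = standardize_columns(Xc[idx])
            Xs = np.asfortranarray(np.column_stack([Xcs, Xs]))
        for k in range(q):
            yb = Y.values[idx, k]
            beta = _fit_standardized(
                Xs, yb, families[k], float(lambda_per_trait[k]), spec.alpha, pf,
                spec.tol, spec.max_iter,
            )
            counts[:, k] += beta[n_cov:] != 0.0

    variant_ids = (
        list(X.variant_ids) if isinstance(X, GenotypeMatrix)
        else [f"snp_{j + 1}" for j in range(p)]
    )
    return SelectionProbabilityMatrix(
        values=counts / float(B),
        lambda_per_trait=lambda_per_trait,
        B=B,
        alpha=spec.alpha,
        trait_ids=list(Y.trait_ids),
        variant_ids=variant_ids,
    )


def write_selection_probabilities(path, S: SelectionProbabilityMatrix) -> None:
    """TSV dump with metadata header lines (#alpha, #B, #lambda_k)."""
    with open(path, "w") as fh:
        fh.write(f"#alpha\t{S.alpha:g}\n")
        fh.write(f"#B\t{S.B}\n")
        lams = "\t".join(f"{l:.10g}" for l in S.lambda_per_trait)
        fh.write(f"#lambda_k\t{lams}\n")
        fh.write("variant_id\t" + "\t".join(S.trait_ids) + "\n")
        for j, vid in enumerate(S.variant_ids):
            row = "\t".join(f"{v:.10g}" for v in S.values[j])
            fh.write(f"{vid}\t{row}\n")
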