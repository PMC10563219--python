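"""Synthetic genotype/phenotype generator for pleiotropy simulation studies.

The generator emulates a SNP-array GWAS panel:

* genotypes are additive counts in {0, 1, 2} with a tunable AR(1) linkage-
  disequilibrium structure, built so that every variant satisfies
  Hardy-Weinberg equilibrium at a minor-allele frequency drawn uniformly
  from a configurable range;
* phenotypes follow a linear model ``y = X beta + eps`` with equicorrelated
  Gaussian errors, a subset of traits dichotomised at their median to give
  binary outcomes;
* true pleiotropic effects live in disjoint regions of adjacent variants,
  each region tied to a pair of traits with either a homogeneous or a
  heterogeneous (reversed) effect profile.

All randomness flows from a single integer seed through named substreams,
so e.g. changing the number of effect regions does not perturb the genotype
draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "SimulationConfig",
    "GenotypeMatrix",
    "PhenotypeTable",
    "SimulationTruth",
    "generate_genotypes",
    "assign_effects",
    "generate_phenotypes",
    "simulate_dataset",
]

# Named substreams hanging off the master seed.  Keeping these fixed means
# each stage of the simulation is reproducible in isolation.
_STREAM_GENOTYPE = 1
_STREAM_MAF = 2
_STREAM_REGIONS = 3
_STREAM_NOISE = 4


def _substream(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(stream,)))


class ConfigurationError(ValueError):
    """Raised when a simulation configuration is internally inconsistent."""


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated GWAS dataset.

    Defaults reproduce the full-scale study conditions: 400 samples,
    40,000 variants, 8 traits (4 quantitative, 4 binary), AR(1) latent
    correlation 0.9, MAF ~ U(0.05, 0.5), 16 disjoint effect regions of 5
    adjacent variants with coefficient magnitudes 0.5 ... 2.5, and error
    correlation drawn once per replicate from U(0, 0.2).
    """

    n: int = 400
    p: int = 40_000
    q: int = 8
    rho_x: float = 0.9
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_regions: int = 16
    region_size: int = 5
    effect_magnitudes: tuple[float, ...] = (0.5, 1.0, 1.5, 2.0, 2.5)
    rho_e_range: tuple[float, float] = (0.0, 0.2)
    trait_split: tuple[int, int] = (4, 4)
    associated_traits: Literal["all", "half"] = "all"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 2 or self.p < 1 or self.q < 1:
            raise ConfigurationError("n >= 2, p >= 1 and q >= 1 are required")
        if not (0.0 <= self.rho_x < 1.0):
            raise ConfigurationError(f"rho_x must lie in [0, 1), got {self.rho_x}")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigurationError(f"maf_range must lie within (0, 0.5], got {self.maf_range}")
        rlo, rhi = self.rho_e_range
        if not (0.0 <= rlo <= rhi < 1.0):
            raise ConfigurationError(f"rho_e_range must lie within [0, 1), got {self.rho_e_range}")
        if self.n_regions * self.region_size > self.p:
            raise ConfigurationError(
                f"{self.n_regions} disjoint regions of {self.region_size} variants "
                f"do not fit into p={self.p}"
            )
        if len(self.effect_magnitudes) != self.region_size:
            raise ConfigurationError("effect_magnitudes must have length region_size")
        if any(m <= 0 for m in self.effect_magnitudes):
            raise ConfigurationError("effect magnitudes must be positive")
        if list(self.effect_magnitudes) != sorted(self.effect_magnitudes):
            raise ConfigurationError("effect_magnitudes must be ascending")
        nq, nb = self.trait_split
        if nq < 0 or nb < 0 or nq + nb != self.q:
            raise ConfigurationError("trait_split counts must be non-negative and sum to q")
        if self.associated_traits not in ("all", "half"):
            raise ConfigurationError("associated_traits must be 'all' or 'half'")
        if self.associated_traits == "half" and self.q < 4:
            raise ConfigurationError("'half' needs at least 4 traits to form pairs")

    @property
    def n_quantitative(self) -> int:
        return self.trait_split[0]

    @property
    def n_binary(self) -> int:
        return self.trait_split[1]

    def trait_ids(self) -> list[str]:
        return [f"trait_{k + 1}" for k in range(self.q)]

    def trait_types(self) -> list[str]:
        # The last n_binary traits are dichotomised; arbitrary but fixed.
        nq = self.n_quantitative
        return ["quantitative"] * nq + ["binary"] * (self.q - nq)


@dataclass
class GenotypeMatrix:
    """Additive genotype codes (n samples x p variants) with metadata."""

    values: np.ndarray  # int8, entries in {0, 1, 2}
    variant_ids: list[str]
    sample_ids: list[str]
    maf: np.ndarray  # length p; simulated truth or empirical estimate

    def __post_init__(self) -> None:
        self.values = np.ascontiguousarray(self.values)
        n, p = self.values.shape
        if len(self.sample_ids) != n or len(self.variant_ids) != p:
            raise ValueError("id lists do not match genotype dimensions")
        if len(self.maf) != p:
            raise ValueError("maf length does not match variant count")
        lo, hi = self.values.min(initial=0), self.values.max(initial=0)
        if lo < 0 or hi > 2:
            raise ValueError("genotype entries must lie in {0, 1, 2}")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_variants(self) -> int:
        return self.values.shape[1]

    def empirical_maf(self) -> np.ndarray:
        return self.values.mean(axis=0) / 2.0


@dataclass
class PhenotypeTable:
    """n x q trait values; binary traits coded 0/1, quantitative traits real."""

    values: np.ndarray  # float64
    trait_types: list[str]  # 'quantitative' | 'binary'
    trait_ids: list[str]
    sample_ids: list[str]
    levels: dict[str, tuple[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.ascontiguousarray(self.values, dtype=np.float64)
        n, q = self.values.shape
        if len(self.trait_types) != q or len(self.trait_ids) != q:
            raise ValueError("trait metadata does not match value dimensions")
        if len(self.sample_ids) != n:
            raise ValueError("sample ids do not match value dimensions")
        for k, kind in enumerate(self.trait_types):
            if kind == "binary":
                col = self.values[:, k]
                if not np.isin(col, (0.0, 1.0)).all():
                    raise ValueError(f"binary trait {self.trait_ids[k]} has values outside {{0,1}}")
            elif kind == "quantitative":
                if not np.isfinite(self.values[:, k]).all():
                    raise ValueError(f"trait {self.trait_ids[k]} has non-finite values")
            else:
                raise ValueError(f"unknown trait type {kind!r}")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_traits(self) -> int:
        return self.values.shape[1]

    def is_binary(self) -> np.ndarray:
        return np.array([t == "binary" for t in self.trait_types])


@dataclass
class SimulationTruth:
    """Ground-truth effect layout: which variants affect which trait pair."""

    beta: np.ndarray  # p x q
    region_layout: list[dict]  # start, stop, traits (pair of indices), pattern
    associated_trait_ids: list[str]

    def positive_indices(self) -> np.ndarray:
        """Indices of variants with any nonzero coefficient (the true pleiotropic set)."""
        return np.flatnonzero(np.any(self.beta != 0.0, axis=1))

    def effect_pairs(self) -> dict[int, tuple[float, float]]:
        """Map variant index -> sorted pair of its two nonzero effect magnitudes."""
        pairs: dict[int, tuple[float, float]] = {}
        for region in self.region_layout:
            a, b = region["traits"]
            for j in range(region["start"], region["stop"]):
                ea, eb = abs(self.beta[j, a]), abs(self.beta[j, b])
                pairs[j] = tuple(sorted((ea, eb)))
        return pairs


def _descending_rank_fraction(z: np.ndarray) -> np.ndarray:
    """zbar[i, j] = (1/n) * #{i' : z[i, j] <= z[i', j]} computed per variant.

    Reference (quadratic-free but sort-based) form of the rank rule; the
    production path in :func:`generate_genotypes` uses an equivalent top-k
    selection, identical whenever the latent draws are tie-free.
    """
    n = z.shape[0]
    order = np.argsort(z, axis=0, kind="stable")
    ranks = np.empty_like(order)
    rows = np.arange(n)[:, None]
    np.put_along_axis(ranks, order, np.broadcast_to(rows, z.shape), axis=0)
    # ranks: 0 for smallest value. #{z_i <= z_i'} = n - rank.
    return (n - ranks) / n


def generate_genotypes(config: SimulationConfig) -> GenotypeMatrix:
    """Simulate HWE genotypes with AR(1) linkage disequilibrium.

    Two independent latent AR(1) Gaussian vectors per sample represent the two
    allele copies.  Each latent value is converted to its within-variant
    empirical rank fraction and compared (strictly) against the variant's MAF,
    so each allele is minor with probability ~MAF while adjacent variants stay
    correlated through the latent process.  With rank fractions on the grid
    {1/n, ..., 1}, exactly ``ceil(n * MAF) - 1`` samples carry each allele
    copy, which the kernel realises by a per-variant top-k selection.
    """
    from uniss._kernels import ar1_inplace, top_k_alleles

    rng_z = _substream(config.seed, _STREAM_GENOTYPE)
    rng_m = _substream(config.seed, _STREAM_MAF)
    maf = rng_m.uniform(config.maf_range[0], config.maf_range[1], size=config.p)
    k_per_variant = (np.ceil(config.n * maf) - 1).astype(np.int64)

    counts = np.zeros((config.p, config.n), dtype=np.int8)
    for _ in range(2):
        z = rng_z.standard_normal((config.p, config.n), dtype=np.float32)
        if config.rho_x != 0.0:
            ar1_inplace(z, config.rho_x)
        top_k_alleles(z, k_per_variant, counts)

    return GenotypeMatrix(
        values=counts.T.copy(),
        variant_ids=[f"snp_{j + 1}" for j in range(config.p)],
        sample_ids=[f"sample_{i + 1}" for i in range(config.n)],
        maf=maf,
    )


def _disjoint_region_starts(rng: np.random.Generator, p: int, n_regions: int, size: int) -> np.ndarray:
    """Starts of ``n_regions`` disjoint length-``size`` windows, uniform over all placements."""
    slack = p - n_regions * size
    # Stars-and-bars bijection: distinct sorted draws from a reduced range map
    # onto disjoint window placements with equal probability each.
    t = np.sort(rng.choice(slack + n_regions, size=n_regions, replace=False))
    return t + np.arange(n_regions) * (size - 1)


def _associated_trait_indices(config: SimulationConfig) -> list[int]:
    if config.associated_traits == "all":
        return list(range(config.q))
    # 'half': keep both trait types represented by taking the first half of
    # the quantitative block and the first half of the binary block.
    nq = config.n_quantitative
    take_q = [k for k in range(nq // 2)]
    n_half = config.q // 2
    take_b = [nq + k for k in range(n_half - len(take_q))]
    return take_q + take_b


def assign_effects(config: SimulationConfig) -> SimulationTruth:
    """Place disjoint effect regions and fill in the true coefficient matrix.

    The associated traits are split into disjoint pairs (after a random
    permutation) and regions are dealt to the pairs round-robin, so every
    associated trait appears in the same number of regions and each trait
    pair accumulates several regions.  Concentrating regions on fixed pairs
    is what produces the strongly correlated trait pairs (sample correlations
    approaching 0.9) characteristic of genuinely pleiotropic traits; spreading
    pairs uniformly would cap every pairwise correlation well below that.

    The first half of the regions carry a homogeneous effect - both traits of
    the pair see the ascending magnitude profile - and the second half a
    heterogeneous effect, where the second trait sees the reversed profile;
    round-robin dealing gives each pair both patterns.
    """
    rng = _substream(config.seed, _STREAM_REGIONS)
    starts = _disjoint_region_starts(rng, config.p, config.n_regions, config.region_size)

    assoc = _associated_trait_indices(config)
    if len(assoc) < 2:
        raise ConfigurationError("need at least two associated traits to form pairs")

    perm = list(rng.permutation(assoc))
    trait_pairs = [(int(perm[2 * i]), int(perm[2 * i + 1])) for i in range(len(perm) // 2)]
    if len(perm) % 2:  # odd leftover trait joins the first pair's partner
        trait_pairs.append((int(perm[-1]), trait_pairs[0][0]))
    n_pairs = len(trait_pairs)

    n_hom = (config.n_regions + 1) // 2
    pairs = [trait_pairs[r % n_pairs] for r in range(config.n_regions)]
    patterns = ["homogeneous" if r < n_hom else "heterogeneous" for r in range(config.n_regions)]

    beta = np.zeros((config.p, config.q))
    mags = np.asarray(config.effect_magnitudes, dtype=float)
    layout: list[dict] = []
    for start, (a, b), pattern in zip(starts, pairs, patterns):
        start = int(start)
        stop = start + config.region_size
        beta[start:stop, a] = mags
        beta[start:stop, b] = mags if pattern == "homogeneous" else mags[::-1]
        layout.append({"start": start, "stop": stop, "traits": (a, b), "pattern": str(pattern)})

    trait_ids = config.trait_ids()
    return SimulationTruth(
        beta=beta,
        region_layout=layout,
        associated_trait_ids=[trait_ids[k] for k in assoc],
    )


def generate_phenotypes(
    X: GenotypeMatrix,
    truth: SimulationTruth,
    config: SimulationConfig,
    *,
    return_latent: bool = False,
):
    """Draw phenotypes ``y = X beta + eps`` with equicorrelated errors.

    A single error correlation ``rho_e`` is drawn per call from
    ``config.rho_e_range`` and shared by all off-diagonal entries of the error
    covariance (unit variances).  Traits designated binary are dichotomised at
    their own median: values strictly greater than the median map to 1.

    With ``return_latent=True`` the pre-dichotomisation continuous matrix is
    returned alongside the table (used e.g. for trait-correlation summaries).
    """
    if X.n_variants != truth.beta.shape[0] or truth.beta.shape[1] != config.q:
        raise ValueError("genotypes, truth and config dimensions disagree")
    rng = _substream(config.seed, _STREAM_NOISE)
    rho_e = float(rng.uniform(config.rho_e_range[0], config.rho_e_range[1]))
    n, q = X.n_samples, config.q
    if not (-1.0 / max(q - 1, 1)) < rho_e < 1.0:
        raise FloatingPointError(f"equicorrelation {rho_e} is not positive definite for q={q}")

    # Equicorrelated N(0, Sigma_e): shared factor + independent noise.
    shared = rng.standard_normal((n, 1))
    indiv = rng.standard_normal((n, q))
    eps = np.sqrt(rho_e) * shared + np.sqrt(1.0 - rho_e) * indiv

    nz = np.flatnonzero(np.any(truth.beta != 0.0, axis=1))
    signalpart = X.values[:, nz].astype(np.float64) @ truth.beta[nz, :]
    latent = signalpart + eps

    values = latent.copy()
    trait_types = config.trait_types()
    levels: dict[str, tuple[str, str]] = {}
    trait_ids = config.trait_ids()
    for k, kind in enumerate(trait_types):
        if kind == "binary":
            med = np.median(values[:, k])
            values[:, k] = (values[:, k] > med).astype(np.float64)
            levels[trait_ids[k]] = ("low", "high")

    table = PhenotypeTable(
        values=values,
        trait_types=trait_types,
        trait_ids=trait_ids,
        sample_ids=list(X.sample_ids),
        levels=levels,
    )
    if return_latent:
        return table, latent
    return table


def simulate_dataset(config: SimulationConfig):
    """Convenience wrapper: genotypes, truth and phenotypes for one replicate."""
    X = generate_genotypes(config)
    truth = assign_effects(config)
    Y = generate_phenotypes(X, truth, config)
    return X, Y, truth
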