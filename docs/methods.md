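# Methods

## The selection problem

A pleiotropic variant is one associated with two or more traits. When the
traits mix quantitative and binary outcomes there is no convenient joint
likelihood to test against, and per-variant meta-analysis ignores linkage
disequilibrium (LD) between variants. This package takes a selection-based
route instead: each trait is modelled by its own penalized regression over
*all* variants simultaneously, and the evidence is pooled on the scale of
*selection probabilities* rather than p-values.

## Model components

### Elastic-net fits and selection probabilities

For trait $k$, the elastic net minimizes a Gaussian or binomial loss plus
the penalty $\lambda\,(\alpha\|\beta\|_1 + \tfrac{1-\alpha}{2}\|\beta\|_2^2)$
in the normalized (mean-loss) convention. The mixing proportion is fixed at
$\alpha = 0.1$: genotype panels are strongly correlated, and a ridge-heavy
mix spreads weight over correlated variants instead of picking one
arbitrarily. $\lambda$ is *not* cross-validated. Each trait gets a 100-value
geometric path from $\lambda_{\max}$ (smallest penalty with an empty
support, from the KKT conditions at zero) down to
$\lambda_{\max}/100$, and the working penalty is the path's lower median
(rank 50 of 100, configurable as any path quantile). Larger penalties leave
too few nonzero coefficients to compare; smaller ones cost compute without
changing the ranking — top-k recovery is empirically flat from the median
down (the suite checks this).

With $B$ bootstrap resamples (default 100; granularity $1/B$), the
selection probability of variant $j$ for trait $k$ is the fraction of
resamples in which $\hat\beta_{jk}(\lambda_k) \ne 0$. One index multiset
per replicate is shared by all traits so trait-wise probabilities face
identical resampling noise. Covariates (e.g. population-cluster
indicators) enter every fit unpenalized and are never counted in supports.

### The unified score

Trait-wise probability sums $S_k = \sum_j s_{jk}$ differ for reasons that
have nothing to do with association (loss family, response scale), so the
probabilities are equalized before pooling. With
$\eta = \min_k S_k$ (rules `max` and `median` are available), each trait's
probabilities are sorted descending and cut at the smallest prefix whose
sum reaches $\eta$; the value at the cut is the trait threshold $\tau_k$.
Survivors ($s_{jk} \ge \tau_k$, the comparison is a plain `>=` with no
epsilon) are rescaled by $\eta/\tilde S_k$ so every trait contributes mass
exactly $\eta$ ($\tilde S_k \ge \eta$ when ties straddle the cut). The
unified score $\pi_j = \sum_k s^*_{jk}$ then lies in $[0, q]$ and, for a
strongly associated variant, approaches the number of traits it is
associated with. Ties in the final ranking break by ascending variant
index; top-k selection includes the whole boundary tie group and reports
the effective k.

Degenerate case: if some trait selects nothing, the min rule forces
$\eta = 0$ and all scores collapse to zero; the code warns, reports the raw
column sums, and suggests `eta_rule="median"`.

### Permutation cut-off

Scores rank variants but do not select. The cut-off $c(\theta)$ is the
average over $T$ permutations (default 100) of the $\theta$-th largest
score computed on row-permuted phenotypes — rows move jointly, so
trait-trait correlation survives while all genotype-phenotype association
is destroyed; covariates stay with the genotype rows. Permuted analyses
reuse the observed per-trait $\lambda$: the null describes the score
distribution at the penalty actually used. Variants with
$\pi_j > c(\theta)$ (strictly) are selected; $\theta$ approximates the
expected number of false selections, playing the role of a significance
level. $c(\theta)$ is non-increasing in $\theta$, so selected sets are
nested.

Calibration caveats, measured in this package's own experiments: on
pure-null data the selected count tracks $\theta$ closely (exchangeability
makes the null exact). With signal present, calibration depends on scale.
At the full simulation scale (p = 40,000, n = 400, moderate LD
$\rho_x = 0.6$) false-selection counts track $\theta$ well. At desk scale
(p = 2,000, n = 200) the cut-off turns markedly conservative: the causal
variants absorb a large share of each elastic-net support, so observed
trait sums fall below their permuted counterparts and the permuted null
tail sits above the observed null tail. Under strong LD ($\rho_x = 0.9$)
the opposite bias appears — LD neighbours of causal variants earn
genuinely high scores that permutation cannot account for, inflating false
selections at small $\theta$.

## The synthetic-data generator

The generator emulates a crop SNP-array panel, not sequence data:

* **Genotypes.** Two independent latent AR(1) Gaussian vectors per sample
  (correlation $\rho_x$, default 0.9, between adjacent variants) represent
  the two allele copies. Per variant, a MAF is drawn once from U(0.05, 0.5)
  and each latent value becomes a minor allele when its within-variant
  empirical rank fraction falls strictly below the MAF. This forces exactly
  $\lceil n\,\mathrm{MAF}\rceil - 1$ carriers per allele copy, yields
  Hardy-Weinberg genotype frequencies per variant (chi-square
  goodness-of-fit rejects at the nominal rate), and gives LD that decays
  geometrically with distance. The production path computes the identical
  rule by per-variant top-k selection (a sort-free equivalence checked in
  the tests).
* **Effects.** Disjoint regions of 5 adjacent variants (default 16 regions)
  carry coefficient magnitudes (0.5, 1.0, 1.5, 2.0, 2.5). Each region is
  tied to a pair of traits; half the regions are *homogeneous* (both traits
  see the ascending profile), half *heterogeneous* (the second trait sees
  the reversed profile, so a variant can be weak for one trait and strong
  for the other). The associated traits are split into fixed disjoint pairs
  and regions are dealt round-robin, concentrating shared signal so that
  paired traits reach sample correlations near 0.9 while unpaired ones stay
  near zero — the correlation profile of genuinely pleiotropic trait sets.
  Spreading pairs uniformly at random would cap every pairwise correlation
  around 0.4 and was rejected for that reason.
* **Phenotypes.** $y = X\beta + \varepsilon$ with equicorrelated unit-variance
  errors; one $\rho_e \sim U(0, 0.2)$ per replicate keeps trait correlation
  from being error-driven alone. The headline correlation summary is the
  mean of the full $q \times q$ sample correlation matrix of the continuous
  traits (what R's `mean(cor(y))` reports), ~0.24 under the default
  configuration, with off-diagonal range roughly $-0.1$ to $0.94$. Traits
  designated binary (the last $B$ columns; default split 4+4) are
  dichotomized at their own median — values strictly above map to 1, giving
  an exact 50/50 split for even $n$ — which is how qualitative crop traits
  (e.g. pod colour scored against a threshold) are emulated.
* **Randomness.** All draws flow from one integer seed through named
  substreams (genotypes / MAFs / regions / noise), so e.g. changing the
  region count does not perturb the genotype matrix, and every replicate of
  an evaluation run is reproducible in isolation.

What the generator does *not* emulate: reference-panel LD structure,
population stratification and admixture, non-uniform MAF spectra, missing
genotypes. Passing tests therefore say nothing about robustness to
population structure (use the covariate hook with real cluster labels) or
to imputation error.

## Numerical choices

* Coordinate descent sweeps features in index order; convergence is
  declared when the largest single-coordinate update in a sweep falls below
  `tol` (default 1e-7), with full-sweep KKT confirmation. The binomial loss
  is handled by IRLS with weights floored at 1e-5.
* The Gaussian response is standardized internally (penalty rescaled by
  sd(y)), the path-solver convention; supports at matched path positions
  are then exactly invariant to rescaling y. Genotype columns are
  standardized to unit 1/n-variance per fit; constant columns (possible in
  bootstrap resamples of rare variants) are dropped by zero-scaling.
* $\lambda_{\max}$ is inflated by a relative 1e-10 so the boundary tie
  "gradient equals threshold" resolves to the empty support.
* A bootstrap replicate in which a binary trait becomes constant is redrawn
  from the same substream; more than $B$ total redraws abort.
* The scaled evaluation preset (n=200, p=2,000, B=50, T=20, R=20) exercises
  the full pipeline in minutes; the full-scale preset (n=400, p=40,000,
  B=T=R=100) reproduces the full-scale study conditions and ships with the
  reference selected-count series as a machine-readable benchmark — it is
  a long-running target, not part of the routine suite.

## Known limitations

* Only two-level qualitative traits are supported (multinomial outcomes are
  out of scope), and the score does not attribute which traits drive a
  variant's selection.
* The permutation cut-off assumes approximate exchangeability between
  observed null variants and permuted variants; both strong LD and small
  panels violate it in opposite directions (see the calibration caveats).
* Missing genotypes are rejected, not imputed; quality control is limited
  to an optional MAF pre-filter (default threshold 1%, following standard
  SNP-array practice).
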