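# uniss — unified selection scores for pleiotropic variants

`uniss` ranks genetic variants by how consistently a penalized regression
selects them across bootstrap resamples *and* across a mix of quantitative
and binary traits, then calibrates a selection cut-off by phenotype
permutation. It is aimed at GWAS-style panels (a few hundred samples,
tens of thousands of SNPs, a handful of heterogeneous traits — e.g. crop
phenotypes such as pod length alongside binary pod colour) where
pleiotropic variants with weak per-trait signals slip past single-trait
tests and meta-analysis ignores linkage disequilibrium.

## The score

For trait $k$ (Gaussian loss for quantitative traits, logistic for binary
ones), an elastic net with mixing $\alpha = 0.1$ is fitted at a fixed
penalty $\lambda_k$ — the median of the trait's own 100-value penalty
path — on each of $B$ bootstrap resamples. The selection probability

$$s_{jk}(\lambda_k) = \frac{1}{B}\sum_{l=1}^{B} I\left(\hat\beta_{jk}(b_l;\lambda_k)\neq 0\right)$$

measures how reliably variant $j$ is picked for trait $k$. Per-trait
probability sums are equalized to $\eta = \min_k S_k$ by thresholding each
trait at $\tau_k$ (the smallest prefix of sorted probabilities reaching
$\eta$) and rescaling survivors by $\eta/\tilde S_k$; the unified score

$$\pi_j = \sum_{k=1}^{q} s^{*}_{jk} \in [0, q]$$

pools the adjusted probabilities and, for strongly associated variants,
approaches the number of traits the variant is associated with. A cut-off
$c(\theta)$ — the average $\theta$-th largest score over $T$
phenotype-permuted reruns — turns the ranking into a selection with about
$\theta$ expected false positives: select $\{j : \pi_j > c(\theta)\}$.

## Worked example

Simulate a small panel with known pleiotropic regions, then score and
select:

```bash
uniss simulate --n 200 --p 2000 --q 8 --q-quant 4 --q-bin 4 \
    --n-regions 4 --rho-x 0.6 --seed 42 --out-prefix demo
uniss run --genotypes demo.genotypes.tsv --phenotypes demo.phenotypes.tsv \
    --b 50 --t 20 --theta 10 --seed 7 --out-prefix demo
```

The manifest (`demo.manifest.json`) contains, among other fields:

```json
{
 "eta": 51.94,
 "tau_per_trait": {"trait_1": 0.02, "trait_2": 0.02, "trait_3": 0.12,
                   "trait_4": 0.06, "trait_5": 0.56, "trait_6": 0.44,
                   "trait_7": 0.44, "trait_8": 0.42},
 "cutoffs": {"10": 2.4059768342889516},
 "n_selected": {"10": 2},
 "bonferroni_reference": 2.5e-05
}
```

`eta` (51.94) is the common probability mass every trait contributes after
adjustment — here the sparsest trait's bootstrap selections sum to ~52.
`tau_per_trait` holds the per-trait selection-probability thresholds (the
binary traits 5–8 run denser supports, hence higher thresholds);
`cutoffs["10"]` is the permutation cut-off at $\theta = 10$; and
`n_selected` says two variants exceed it — `demo.selected.tsv` names them:

```
theta   variant_id   score
10      snp_1840     3.320901608
10      snp_1519     2.678805216
```

with the full ranking in `demo.scores.tsv`. The Bonferroni line is only a
familiar yardstick (0.05/p); the method itself never computes p-values.

In Python the same pipeline is three calls:

```python
from uniss import (SimulationConfig, simulate_dataset,
                   selection_probabilities, unified_scores,
                   permutation_cutoff, select_variants)

X, Y, truth = simulate_dataset(SimulationConfig(n=200, p=2000, seed=42))
S = selection_probabilities(X, Y, B=50, seed=7)
result = unified_scores(S)                       # result.pi, result.order
null = permutation_cutoff(X, Y, B=50, T=20, theta_values=(10,),
                          lambda_per_trait=S.lambda_per_trait, seed=7)
selected = select_variants(result, null.cutoffs[10])
```

Real data enter through `uniss.io.read_genotypes` (PLINK `.raw`, TSV, or
biallelic VCF; missing genotypes must be imputed upstream) and
`read_phenotypes` (TSV with a `#type:` row tagging traits
quantitative/binary). Population-structure covariates are passed
unpenalized via `--covariates`.

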