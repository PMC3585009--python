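# gggtest — gene-based gene–gene interaction tests for quantitative traits

Marker-by-marker epistasis scans in GWAS pay an enormous multiple-testing
price and lose power when causal variants are only tagged. `gggtest`
implements **gene-based gene–gene interaction (GGG) tests**: every pairwise
SNP×SNP interaction between two genes is tested with the linear model

    y = b0 + b1·s1 + b2·s2 + b3·(s1·s2) + covariates + e,     H0: b3 = 0

and the m1·m2 resulting P values are combined into a *single* gene-level
P value. Because within-gene linkage disequilibrium (LD) correlates the
pairwise tests, the combination uses their null correlation matrix Σ,
derived analytically from the genotypes (or, without individual-level
data, from reference-panel LD plus a simulation-calibrated polynomial).

Four combiners are provided, plus a principal-components baseline:

| method | idea | P value |
|--------|------|---------|
| `minP` | minimum P value | MVN rectangle probability under Σ |
| `GATES` | extended Simes | effective-test counts from Σ |
| `tTS` | truncated tail strength (Σ of weighted exceedances below τ) | adaptive MVN sampling |
| `tProd` | truncated product of P values below τ | adaptive MVN sampling |
| `PC` | F-test on products of gene-level principal components | exact F |

The truncated tests aggregate several moderately significant SNP pairs and
are the most powerful choices when interacting variants are untyped or when
several pairs interact; `minP`/`GATES` win when a single interacting pair is
directly genotyped. The package is aimed at statistical geneticists running
hypothesis-driven interaction scans (e.g. across protein–protein interaction
gene pairs) and at methodologists who need the correlation machinery.

## Worked example

```python
import numpy as np
from gggtest import (all_pairs_tests, corr_tests_from_genotypes, gg_gates,
                     gg_minp, gg_tts, gg_tprod, default_scenario,
                     simulate_genotypes, simulate_phenotype)

# two LD-structured loci (53 and 28 SNPs), one observed causal interacting pair
spec = default_scenario(n=2000, causal_pairs=((29, 17),), effect_size=0.4)
g1, g2 = simulate_genotypes(spec, seed=11)
y = simulate_phenotype((g1, g2), spec, seed=12)

# test the 14 x 10 tag SNPs
t1, t2 = spec.locus1.tag_idx0, spec.locus2.tag_idx0
tags1, tags2 = g1.select(t1), g2.select(t2)
pvals = np.array([r.p_two_sided for r in all_pairs_tests(y, tags1, tags2)])
sigma = corr_tests_from_genotypes(tags1, tags2)

print("smallest pairwise P:", f"{pvals.min():.3g}")
print("minP :", f"{gg_minp(pvals, sigma, seed=1).p_gene:.3g}")
print("GATES:", f"{gg_gates(pvals, sigma).p_gene:.3g}")
print("tTS  :", f"{gg_tts(pvals, sigma, seed=1).p_gene:.3g}")
print("tProd:", f"{gg_tprod(pvals, sigma, seed=1).p_gene:.3g}")
```

Output:

```
smallest pairwise P: 1.2e-06
minP : 0.000167
GATES: 0.000153
tTS  : 0.302
tProd: 0.203
```

How to read it: the causal pair is directly genotyped (both SNPs are
tags), so the single strongest pairwise signal (P = 1.2e-6) carries the
interaction, and after correcting for the 140 correlated pairwise tests
through Σ, `minP` and `GATES` return a gene-level P ≈ 1.6e-4 from one
test per gene pair. The truncated tests, which spread their attention
over every pair below τ, dilute this lone signal (P ≈ 0.2–0.3) — the
mirror image of their advantage when several pairs, or untyped variants
tagged by several pairs, drive the interaction.

A shell-level scan over a gene-pair list:

```bash
ggg scan --geno study.vcf --pheno hdl.tsv --covar covars.tsv \
         --genes genes.tsv --pairs ppi_pairs.tsv \
         --methods minP,GATES,tTS,tProd --tau 0.05 --chunk 500 \
         --seed 7 --out results.tsv
ggg simulate --mode type1 --reps 2000 --seed 1
ggg calibrate-poly --reps 4000 --seed 1
```

Gene pairs with more than 500 SNP pairs are split into contiguous ≤500-pair
chunks, each reported (and Bonferroni-counted) as its own test; interrupted
scans resume from the last written row.

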