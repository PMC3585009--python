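# Methods

`gggtest` tests for statistical interaction (epistasis) between two *genes*
on a quantitative trait by combining all pairwise SNP×SNP interaction tests
between them into one gene-level P value. This note describes the model,
the correlation machinery that makes the combination valid, the synthetic
data used to validate it, and the numerical and design choices.

## The marker-level model

For individuals i = 1..n with additive dosages s1, s2 at one SNP from each
gene, the trait is modelled as

    y_i = b0 + b1 s1_i + b2 s2_i + b3 s1_i s2_i + c'x_i + e_i,   e ~ N(0, σ²)

and the interaction is the Wald t-test of H0: b3 = 0 with n − (4 + c)
residual degrees of freedom (c = number of covariates). Between two genes
with m1 and m2 SNPs there are q = m1·m2 such tests. Dosages are reference-
allele counts in [0, 2]; imputed (fractional) dosages are accepted.
Missing dosages are mean-imputed per SNP at read time; individuals with
missing phenotype or covariates are dropped listwise. The two genes are
assumed to be in linkage equilibrium with each other — the correlation
machinery below models only *within*-gene LD.

All q fits are computed in one vectorized pass: covariates and intercept
are projected out of the trait, the dosages and the raw dosage products
(Frisch–Waugh), leaving a 3-parameter regression per pair whose normal
equations are assembled by einsums and solved batched. Pairs whose design
is numerically singular (condition number of X'X above 1e12, e.g. a SNP
paired with itself) are flagged and skipped, not fatal.

## Correlation between interaction tests (Σ)

Within-gene LD makes the q t-statistics correlated under the null. With
individual-level genotypes the null correlation between two interaction
tests has a closed form: row 4 of (X'X)⁻¹X' equals u'/(u'u), where u is
the residual of the product term on the rest of the design, so the
normalized cross-product of two tests' interaction rows reduces to
corr(u, v) — the correlation between the two residualized product
columns. Σ is therefore the sample correlation matrix of the q
residualized products: symmetric, unit-diagonal, and positive
semidefinite by construction. With covariates, dosages are residualized
on them first; Σ is a property of the designs only and never touches the
phenotype. This construction was validated against Monte-Carlo
correlations of actual null t statistics (50 LD configurations × 10,000
replicates; max absolute deviation < 0.05, regression slope ≈ 1 — see
`tests/test_acceptance.py`).

When only summary LD is available (reference-panel r and allele
frequencies), Σ is approximated in two steps. First the correlation
between the two SNP *products* from the independent-product moment
identity under Hardy–Weinberg moments (μ = 2f, s² = 2f(1−f)):

    Cov(P1, P2) = Cov1·Cov2 + Cov1·μ21·μ22 + Cov2·μ11·μ12,
    Var(P)     = s1²s2² + s1²μ2² + s2²μ1²,

with Cov_i = r_i s_i1 s_i2. Second, a fifth-degree zero-intercept
polynomial maps product correlation to statistic correlation:

    y = 0.33181x − 2.50443x² + 10.21850x³ − 11.09725x⁴ + 4.05560x⁵.

The polynomial was estimated by simulation on magnitudes in [0, 1]; we
apply it to |x| and restore the sign, clip the result to [−1, 1] (the
polynomial reaches 1.00423 at x = 1), and repair the matrix to PSD by
eigenvalue clipping with unit-diagonal rescaling. **Limitation:** the
product correlation is only informative when the two within-gene LD
coefficients are sign-consistent (both positive under the usual
frequency-aligned allele coding). For opposite-sign or both-negative LD
the mean-driven covariance terms cancel the LD term and the product
correlation collapses toward zero while the statistic correlation does
not; no function of the product correlation can recover it. Use the
genotype route whenever individual-level data exist.

`calibrate_polynomial` refits this curve from scratch: for a grid of
sign-consistent LD configurations spanning |r| ∈ [0.1, 0.95] and
f ∈ [0.05, 0.5] it simulates HWE genotype quadruples (Gaussian-copula
thresholding, with the latent correlation solved numerically so the
realized dosage correlation hits its target), estimates the statistic
correlation from null-phenotype t-statistic pairs, and fits the
polynomial by least squares. The refit R² (centered) is ≈ 0.985 at the
defaults (n = 1000 individuals, 4000 null replicates per configuration).
Mid-curve values are grid-density-dependent; only the fit quality and the
end points are stable quantities.

## Gene-level combination

Given the q two-sided P values and Σ:

* **minP** — refers P_min to the multivariate-normal rectangle
  probability: p_gene = 1 − Pr(|Z_i| < Φ⁻¹(1 − P_min/2) ∀i),
  Z ~ MVN(0, Σ). The integral uses the Genz separation-of-variables
  transformation with scrambled-Sobol points and Cranley–Patterson
  rotations (deterministic given the seed; 4096 points × 2 shifts by
  default, relative error well under 1e-3 at gene-level scales; the
  simulation harness uses 512 × 1). The result is clamped to the
  rigorous Bonferroni envelope [P_min, q·P_min], which also absorbs
  integration noise. With q = 1 it reduces exactly to the marker test;
  with Σ = I it reproduces the Šidák formula.

* **GATES** — extended Simes: with P ascending,
  p_gene = min_j m_e p_(j) / m_e(j), where the effective test counts use
  the Moskvina–Schmidt prefix-maximum rule
  m_e(j) = 1 + Σ_{i=2..j} √(1 − max_{l<i} ρ²_{il}) over the ordered
  tests, with Σ entries used directly as statistic correlations.
  Reduces to Simes for Σ = I and to P_min under total correlation.

* **tTS** — truncated tail strength: Σ_j 1{p_(j) ≤ τ}(1 − p_(j)(m+1)/j),
  larger = more significant. The constant 1/m prefactor of the original
  tail strength is dropped; empirical-P ranking is invariant to it, so
  statistics are comparable across runs only at equal m.

* **tProd** — truncated product: Π p_j over p_j ≤ τ (evaluated in logs),
  smaller = more significant.

τ defaults to 0.05. The two truncated statistics have no tractable null
under dependence, so their P values are empirical: draw Z ~ MVN(0, Σ)
(Cholesky precomputed once; a tiny ridge or eigenvalue clipping handles
singular Σ from duplicated SNPs), convert to two-sided P values by the
normal approximation (the t-to-normal error is negligible at n ≥ 1000),
evaluate the statistic per draw, and report the tie-inclusive proportion
at least as extreme, floored at 1/draws. The adaptive schedule draws
1000 vectors, adds 99,000 when the running estimate is < 0.01, and adds
99,900,000 more when it is < 1e-4: ceiling 10⁸ draws, smallest
attainable empirical P 1e-8. Only entries with |z| above the two-sided
τ quantile are converted to P values — nothing else can enter either
truncated statistic — which is what makes the escalated stages
affordable. The simulation harness caps the schedule at 10⁵ draws:
empirical-P resolution of 1e-5 is ample for rejection decisions at
α ≥ 0.01, and escalation cannot change a decision made at those levels.

* **PC baseline** — each gene's covariate-residualized, standardized
  dosages are collapsed to the smallest PC set explaining ≥ 90% of
  variance (SVD); the interaction is the nested-model F-test on all
  L1·L2 PC products with (L1·L2, n − p) df. It errors out when
  L1·L2 ≥ n/10 (overparameterized). Included as the power comparison,
  not as a recommended test.

Gene pairs with more than 500 SNP pairs are split into contiguous blocks
(products of contiguous SNP ranges in genomic order, preserving
within-chunk LD) of at most 500 pairs; each chunk is its own gene-level
test and counts separately toward the Bonferroni correction
α / (chunk-level tests × traits). Chunk P values are deliberately not
re-combined.

## Synthetic data

The generator emulates two loci sampled from a finite cohort: per locus,
a pool of 20,000 haplotypes is drawn from a Gaussian copula with latent
autoregressive correlation 0.8^|i−j| thresholded at each SNP's
allele-frequency quantile, then paired into 10,000 diploid individuals;
every replicate samples its n individuals from the pool without
replacement. The default loci carry 53 and 28 SNPs with 14 and 10 tag
SNPs; only tags are tested, so causal SNPs are either Observed (tags) or
Untyped. Causal-SNP frequencies are fixed targets (realized pool
frequencies within ±0.01); the remaining frequencies are a frozen
U(0.10, 0.50) draw, part of the locus definition. Tag spacing is mixed —
several adjacent pairs — mirroring tag sets inside LD blocks, which keeps
moderate tag–tag LD and a stable PC count (L1·L2 = 88 at the defaults).

Phenotypes: under the null, pure N(0, 1) noise; under an alternative,
y = Σ_pairs (b1·Sa + b2·Sb + b3·Sa·Sb) + e with e ~ N(0,1) and
b1 = b2 = b3 by default. `run_type1` and `run_power` tabulate rejection
proportions with binomial Monte-Carlo standard errors; the same seed
gives bit-identical reports. External-LD mode computes Σ once from an
independently seeded reference pool (the reference-panel situation).

What the generator does **not** emulate: the block structure, long-range
LD and allele-frequency spectrum of real cohort loci. The copula's LD
decays geometrically, so tag–causal correlation is weaker than for
tag SNPs chosen against dense real haplotypes. Consequently absolute
power at a given (n, effect size) is lower than published cohort-based
numbers, and power results should be read as *orderings and trends*
(which method beats which, monotonicity in n and effect), not as
point estimates. One ordering is LD-regime-dependent: with strong
tag–causal LD the PC baseline is the least powerful method everywhere,
but under this generator's attenuated LD the P-value combiners lose
proportionally more power than the PC F-test (which aggregates all
products), and PC can overtake the truncated tests in the
single-observed-pair scenario and the best-signal tests at large n —
the shipped power study reports exactly this. Type-I error, the
correlation-formula validation and the polynomial calibration do not
depend on this caveat.

## Numerical choices and degenerate inputs

* P values from the marker tests use the exact t distribution; the
  combination stage uses the normal approximation (matching the MVN null).
* Collinearity cutoff: condition number of X'X > 1e12.
* Σ eigenvalue floor 1e-10 in PSD repair; repair is a no-op for matrices
  PSD within 1e-8. Genotype-route Σ needs no repair by construction.
* Empirical-P tie rule: "at least as extreme" (≥ for tTS, ≤ for tProd),
  no pseudo-count, floor 1/draws.
* Duplicated SNPs give singular Σ blocks (handled by the ridge/clipping)
  and unit correlations (preserved by repair).
* An interaction statistic that is non-finite raises; a pair with a
  singular design inside a batch is flagged and excluded from both the
  P vector and Σ.
* minP's QMC seed, the sampler seed and stage counts are recorded in the
  result metadata.

## Problem sizes used in the shipped studies

Desk-scale defaults keep full studies tractable on one core: 2,000 null
replicates per sample size for type-I calibration, 500 replicates per
power scenario, 42 configurations × 4000 replicates for the polynomial
refit, 50 configurations × 10,000 replicates for the correlation-formula
validation, 10⁵-draw ceilings inside simulation loops. Full-scale runs
(10,000/5,000 replicates, 10⁸-draw ceiling) are available through
`ScenarioSpec`/`TruncationConfig`.

## Known limitations

* Quantitative traits only; the case-control/logistic extension would
  need a different correlation derivation.
* No dominance terms or three-way interactions.
* External-LD route: sign-consistent LD only (see above); haplotype-phase
  measures (D′) are not used.
* Cross-gene LD is assumed absent; do not apply to physically adjacent
  loci.
* Tag lists are inputs; the package does not select tags.
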