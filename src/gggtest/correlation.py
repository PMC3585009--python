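"""Correlation structure of the pairwise interaction test statistics.

Within-gene linkage disequilibrium makes the m1*m2 interaction t-tests
between two genes correlated under the null. This module builds that
q x q correlation matrix (q = m1*m2) two ways:

* from individual-level genotypes: the null correlation between two
  interaction t statistics equals the correlation between the two
  interaction-term regressors after projecting out the intercept, the two
  main effects and any covariates (row 4 of (X'X)^-1 X' is u'/(u'u) with u
  that residual, so the normalized cross-product of the two interaction
  rows collapses to corr(u, v));

* from external LD summaries (signed dosage correlation r per within-gene
  SNP pair plus reference allele frequencies): first the correlation
  between the two SNP *products* from the independent-product moment
  identity under Hardy-Weinberg moments (mu = 2f, s^2 = 2f(1-f)), then a
  fifth-degree zero-intercept polynomial, estimated by simulation, mapping
  product correlation to test-statistic correlation.

The genotype route is exact (and was validated against Monte-Carlo
correlations of actual t statistics; see the test suite); the external
route is the fallback when only summary data are available.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np

from ._core import PairDesigns
from .datatypes import CovariateTable, GenotypeMatrix

__all__ = [
    "SigmaMatrix",
    "corr_tests_from_genotypes",
    "corr_products_external",
    "poly_map",
    "sigma_from_external_ld",
    "repair_psd",
    "POLY_COEFFS",
]

# Fifth-degree zero-intercept polynomial mapping |product correlation| to
# |test-statistic correlation|, coefficients for x^1 ... x^5.
POLY_COEFFS = np.array([0.33181, -2.50443, 10.21850, -11.09725, 4.05560])


@dataclass
class SigmaMatrix:
    """Correlation matrix among the m1*m2 interaction test statistics."""

    values: np.ndarray  # q x q
    source: str  # "genotypes" | "external-ld"
    pair_index: List[Tuple[int, int]]  # row -> (gene-1 SNP idx, gene-2 SNP idx)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        q = self.values.shape[0]
        if self.values.shape != (q, q) or len(self.pair_index) != q:
            raise ValueError("SigmaMatrix shape does not match pair index")

    @property
    def q(self) -> int:
        return self.values.shape[0]

    def submatrix(self, rows: np.ndarray) -> "SigmaMatrix":
        rows = np.asarray(rows, dtype=int)
        return SigmaMatrix(
            values=self.values[np.ix_(rows, rows)],
            source=self.source,
            pair_index=[self.pair_index[r] for r in rows],
        )


def _pair_index(m1: int, m2: int) -> List[Tuple[int, int]]:
    return [(i, j) for i in range(m1) for j in range(m2)]


def corr_tests_from_genotypes(
    geno1: GenotypeMatrix,
    geno2: GenotypeMatrix,
    covars: Optional[CovariateTable] = None,
) -> SigmaMatrix:
    """Sigma from individual-level genotypes.

    Row/column order is row-major in gene-1 SNPs, matching
    :func:`gggtest.marker.all_pairs_tests`. Being a sample correlation
    matrix of residual vectors, the result is positive semidefinite by
    construction.
    """
    C = None if covars is None else covars.values
    designs = PairDesigns(geno1.dosages, geno2.dosages, C)
    U = designs.U
    norms = np.linalg.norm(U, axis=0)
    norms[norms == 0] = 1.0
    Un = U / norms
    values = np.clip(Un.T @ Un, -1.0, 1.0)
    np.fill_diagonal(values, 1.0)
    return SigmaMatrix(
        values=values,
        source="genotypes",
        pair_index=_pair_index(geno1.n_snps, geno2.n_snps),
    )


def corr_products_external(r1: float, r2: float, f) -> float:
    """Correlation between two SNP products from summary LD.

    ``r1`` is the signed dosage correlation between the two gene-1 SNPs,
    ``r2`` between the two gene-2 SNPs, and ``f`` the four reference allele
    frequencies ordered (gene1 SNP a, gene1 SNP b, gene2 SNP a, gene2 SNP b).
    Assumes Hardy-Weinberg moments and linkage equilibrium between genes.
    """
    f = np.asarray(f, dtype=float)
    if f.shape != (4,):
        raise ValueError("need exactly four allele frequencies")
    if np.any((f <= 0) | (f >= 1)):
        raise ValueError("allele frequencies must lie in (0, 1)")
    if not (-1 <= r1 <= 1 and -1 <= r2 <= 1):
        raise ValueError("correlations must lie in [-1, 1]")
    mu = 2.0 * f
    s = np.sqrt(2.0 * f * (1.0 - f))
    cov1 = r1 * s[0] * s[1]
    cov2 = r2 * s[2] * s[3]
    # products P1 = S_1a * S_2a, P2 = S_1b * S_2b with independent genes
    cov = cov1 * cov2 + cov1 * mu[2] * mu[3] + cov2 * mu[0] * mu[1]
    var1 = s[0] ** 2 * s[2] ** 2 + s[0] ** 2 * mu[2] ** 2 + s[2] ** 2 * mu[0] ** 2
    var2 = s[1] ** 2 * s[3] ** 2 + s[1] ** 2 * mu[3] ** 2 + s[3] ** 2 * mu[1] ** 2
    return float(cov / np.sqrt(var1 * var2))


def poly_map(product_corr):
    """Map product correlation to test-statistic correlation.

    The polynomial was estimated on magnitudes in [0, 1]; it is applied to
    |x| and the sign of x is restored. Values may slightly exceed 1 near
    x = 1 (the polynomial evaluates to 1.00423 there); callers building a
    Sigma matrix clip to [-1, 1] afterwards.
    """
    x = np.asarray(product_corr, dtype=float)
    if np.any(np.abs(x) > 1 + 1e-12):
        raise ValueError("product correlation outside [-1, 1]")
    ax = np.abs(x)
    powers = np.stack([ax ** k for k in range(1, 6)], axis=-1)
    out = np.sign(x) * (powers @ POLY_COEFFS)
    return out if out.ndim else float(out)


def sigma_from_external_ld(
    ld1: np.ndarray,
    ld2: np.ndarray,
    freq1: np.ndarray,
    freq2: np.ndarray,
) -> SigmaMatrix:
    """Sigma from per-gene signed LD matrices and allele frequencies.

    ``ld1`` (m1 x m1) and ``ld2`` (m2 x m2) hold signed dosage correlations
    within each gene, e.g. from a reference panel; ``freq1``/``freq2`` the
    per-SNP reference allele frequencies. Entries are the polynomial image
    of the product correlation, clipped to [-1, 1], then PSD-repaired.
    """
    ld1 = np.asarray(ld1, dtype=float)
    ld2 = np.asarray(ld2, dtype=float)
    f1 = np.asarray(freq1, dtype=float)
    f2 = np.asarray(freq2, dtype=float)
    m1, m2 = f1.size, f2.size
    if ld1.shape != (m1, m1) or ld2.shape != (m2, m2):
        raise ValueError("LD matrix shapes do not match frequency vectors")
    if np.any((f1 <= 0) | (f1 >= 1)) or np.any((f2 <= 0) | (f2 >= 1)):
        raise ValueError("allele frequencies must lie in (0, 1)")
    mu1, s1 = 2.0 * f1, np.sqrt(2.0 * f1 * (1.0 - f1))
    mu2, s2 = 2.0 * f2, np.sqrt(2.0 * f2 * (1.0 - f2))
    cov1 = ld1 * np.outer(s1, s1)  # m1 x m1, entry (a, b)
    cov2 = ld2 * np.outer(s2, s2)
    # cov(P_ij, P_kl) = cov1[i,k] cov2[j,l] + cov1[i,k] mu2[j] mu2[l]
    #                 + cov2[j,l] mu1[i] mu1[k]
    cov = (
        np.einsum("ik,jl->ijkl", cov1, cov2)
        + np.einsum("ik,j,l->ijkl", cov1, mu2, mu2)
        + np.einsum("jl,i,k->ijkl", cov2, mu1, mu1)
    )
    var = s1[:, None] ** 2 * s2[None, :] ** 2 + np.outer(s1 ** 2, mu2 ** 2) + np.outer(
        mu1 ** 2, s2 ** 2
    )
    sd = np.sqrt(var).ravel()
    q = m1 * m2
    prod_corr = cov.reshape(q, q) / np.outer(sd, sd)
    prod_corr = np.clip(prod_corr, -1.0, 1.0)
    values = np.clip(poly_map(prod_corr), -1.0, 1.0)
    np.fill_diagonal(values, 1.0)
    sig = SigmaMatrix(values=values, source="external-ld", pair_index=_pair_index(m1, m2))
    return repair_psd(sig)


def repair_psd(sigma: SigmaMatrix, tol: float = 1e-8) -> SigmaMatrix:
    """Clip negative eigenvalues and rescale to unit diagonal.

    The matrix is returned unchanged when its smallest eigenvalue is
    >= -tol; otherwise eigenvalues are floored at 1e-10 and the result is
    rescaled back to a correlation matrix.
    """
    V = (sigma.values + sigma.values.T) / 2.0
    w, Q = np.linalg.eigh(V)
    if w.min() >= -tol:
        return sigma
    w = np.clip(w, 1e-10, None)
    fixed = (Q * w) @ Q.T
    d = np.sqrt(np.diag(fixed))
    fixed = fixed / np.outer(d, d)
    np.fill_diagonal(fixed, 1.0)
    return SigmaMatrix(values=fixed, source=sigma.source, pair_index=sigma.pair_index)
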