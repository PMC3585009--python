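"""Per-SNP-pair interaction t-tests.

For each pair of SNPs, one from each gene, the quantitative trait is
modelled as

    y = b0 + b1*s1 + b2*s2 + b3*(s1*s2) + (covariates) + e,   e ~ N(0, s^2)

and the interaction is the Wald t-test of H0: b3 = 0 with n - (4 + c)
residual degrees of freedom. The two genes are assumed to be in linkage
equilibrium with each other; no check is enforced.

Missing dosages are expected to have been mean-imputed upstream (see
:func:`gggtest.io.read_genotypes`); individuals missing phenotype or
covariates are dropped listwise before reaching this module.
"""
from __future__ import annotations

from typing import List, Optional

import numpy as np

from ._core import PairDesigns, batched_interaction_fit, residualize
from .datatypes import (
    CollinearityError,
    CovariateTable,
    GenotypeMatrix,
    PairTestResult,
    PhenotypeVector,
)

__all__ = ["fit_interaction", "all_pairs_tests"]


def _covar_values(covars: Optional[CovariateTable]) -> Optional[np.ndarray]:
    if covars is None:
        return None
    return covars.values


def fit_interaction(
    y: PhenotypeVector,
    s1: np.ndarray,
    s2: np.ndarray,
    covars: Optional[CovariateTable] = None,
    snp1: str = "snp1",
    snp2: str = "snp2",
) -> PairTestResult:
    """Interaction t-test for a single SNP pair.

    Raises :class:`CollinearityError` when the product term is numerically
    collinear with the main effects (condition number of X'X above 1e12),
    and :class:`SampleSizeError` when n < 10x the parameter count.
    """
    s1 = np.asarray(s1, dtype=float).ravel()
    s2 = np.asarray(s2, dtype=float).ravel()
    yv = y.values
    if not (s1.size == s2.size == yv.size):
        raise ValueError("phenotype and dosage vectors differ in length")
    if s1.std() == 0 or s2.std() == 0:
        raise CollinearityError(f"constant dosage column in pair ({snp1}, {snp2})")
    C = _covar_values(covars)
    designs = PairDesigns(s1[:, None], s2[:, None], C)
    if designs.singular[0]:
        raise CollinearityError(
            f"design matrix for pair ({snp1}, {snp2}) is numerically singular "
            "(product term collinear with main effects)"
        )
    y_resid = residualize(yv, C)
    b3, se, t, p = batched_interaction_fit(designs, y_resid)
    return PairTestResult(
        snp1=snp1,
        snp2=snp2,
        b3_hat=float(b3[0]),
        se_b3=float(se[0]),
        t_stat=float(t[0]),
        df=designs.df,
        p_two_sided=float(p[0]),
    )


def all_pairs_tests(
    y: PhenotypeVector,
    geno1: GenotypeMatrix,
    geno2: GenotypeMatrix,
    covars: Optional[CovariateTable] = None,
) -> List[PairTestResult]:
    """All m1*m2 pairwise interaction tests, row-major in gene-1 SNPs.

    The result order — (1,1), (1,2), ..., (1,m2), (2,1), ... — matches the
    row/column order of the Sigma matrix from
    :func:`gggtest.correlation.corr_tests_from_genotypes`.

    Pairs with singular designs are returned as flagged results
    (``error`` set, statistics NaN) rather than aborting the batch.
    """
    C = _covar_values(covars)
    designs = PairDesigns(geno1.dosages, geno2.dosages, C)
    y_resid = residualize(y.values, C)
    b3, se, t, p = batched_interaction_fit(designs, y_resid)
    results: List[PairTestResult] = []
    q = 0
    for i in range(geno1.n_snps):
        for j in range(geno2.n_snps):
            err = None
            if designs.singular[q]:
                err = (
                    f"design matrix for pair ({geno1.snp_ids[i]}, "
                    f"{geno2.snp_ids[j]}) is numerically singular"
                )
            results.append(
                PairTestResult(
                    snp1=geno1.snp_ids[i],
                    snp2=geno2.snp_ids[j],
                    b3_hat=float(b3[q]),
                    se_b3=float(se[q]),
                    t_stat=float(t[q]),
                    df=designs.df,
                    p_two_sided=float(p[q]),
                    error=err,
                )
            )
            q += 1
    return results


def pairwise_pvalues(
    y: PhenotypeVector,
    geno1: GenotypeMatrix,
    geno2: GenotypeMatrix,
    covars: Optional[CovariateTable] = None,
) -> np.ndarray:
    """Fast path: the m1*m2 two-sided P values only, row-major."""
    C = _covar_values(covars)
    designs = PairDesigns(geno1.dosages, geno2.dosages, C)
    y_resid = residualize(y.values, C)
    return batched_interaction_fit(designs, y_resid)[3]
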