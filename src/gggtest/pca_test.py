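"""Principal-components gene-gene interaction test (the power baseline).

Each gene's (covariate-residualized, standardized) dosages are collapsed to
the smallest set of principal components explaining >= 90% of the variance.
The interaction is then the nested-model F-test comparing

    full:    y ~ 1 + covars + PCs(gene1) + PCs(gene2) + all PC products
    reduced: y ~ 1 + covars + PCs(gene1) + PCs(gene2)

with (L1*L2, n - p_full) degrees of freedom — a test of pure interaction
on top of any marginal effects. Collapsing first averages out heterogeneous
signals, which is why this test trails the P-value combiners in power.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy import stats

from ._core import residualize
from .datatypes import CovariateTable, GenePairResult, GenotypeMatrix, PhenotypeVector

__all__ = ["PCBasis", "gene_pc_basis", "gg_pc_test"]


@dataclass
class PCBasis:
    """Retained principal components of one gene's standardized dosages."""

    loadings: np.ndarray  # m x L, orthonormal columns
    explained_fraction: np.ndarray  # per retained component
    L: int


def _standardized(geno: GenotypeMatrix, covars: Optional[CovariateTable]) -> np.ndarray:
    X = residualize(geno.dosages, None if covars is None else covars.values)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    return X / sd


def _pc_decompose(X: np.ndarray, var_explained: float) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """SVD-based PCA; returns (scores, loadings, explained fractions) for the
    smallest component set reaching ``var_explained`` cumulative variance."""
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    frac = s**2 / np.sum(s**2)
    L = int(np.searchsorted(np.cumsum(frac), var_explained - 1e-12) + 1)
    L = min(L, frac.size)
    return U[:, :L] * s[:L], Vt[:L].T, frac[:L]


def gene_pc_basis(
    geno: GenotypeMatrix,
    covars: Optional[CovariateTable] = None,
    var_explained: float = 0.90,
) -> PCBasis:
    """Smallest PC set with cumulative explained variance >= ``var_explained``."""
    _, loadings, frac = _pc_decompose(_standardized(geno, covars), var_explained)
    return PCBasis(loadings=loadings, explained_fraction=frac, L=loadings.shape[1])


def _rss(X: np.ndarray, y: np.ndarray) -> float:
    # normal equations with a tiny ridge: PC designs are well conditioned
    XtX = X.T @ X
    XtX[np.diag_indices_from(XtX)] += 1e-10
    beta = np.linalg.solve(XtX, X.T @ y)
    return float(y @ y - beta @ (X.T @ y))


def gg_pc_test(
    y: PhenotypeVector,
    geno1: GenotypeMatrix,
    geno2: GenotypeMatrix,
    covars: Optional[CovariateTable] = None,
    var_explained: float = 0.90,
    gene1: str = "gene1",
    gene2: str = "gene2",
) -> GenePairResult:
    """Nested-model F-test for interaction between gene-level PCs."""
    n = y.n
    S1, _, _ = _pc_decompose(_standardized(geno1, covars), var_explained)
    S2, _, _ = _pc_decompose(_standardized(geno2, covars), var_explained)
    L1, L2 = S1.shape[1], S2.shape[1]
    if L1 * L2 >= n / 10:
        raise ValueError(
            f"overparameterized PC interaction model: L1*L2 = {L1 * L2} >= n/10"
        )
    prods = np.einsum("ni,nj->nij", S1, S2).reshape(n, L1 * L2)
    C = None if covars is None else covars.values
    base_cols = [np.ones((n, 1))]
    if C is not None:
        base_cols.append(C)
    reduced = np.concatenate(base_cols + [S1, S2], axis=1)
    full = np.concatenate([reduced, prods], axis=1)
    df_num = L1 * L2
    df_den = n - full.shape[1]
    if df_den < 1:
        raise ValueError("not enough residual degrees of freedom for the F-test")
    rss_reduced = _rss(reduced, y.values)
    rss_full = _rss(full, y.values)
    F = ((rss_reduced - rss_full) / df_num) / (rss_full / df_den)
    p = float(stats.f.sf(F, df_num, df_den))
    return GenePairResult(
        gene1=gene1, gene2=gene2, method="PC",
        statistic=float(F), p_gene=p, n_pairs=geno1.n_snps * geno2.n_snps,
        extra={"L1": L1, "L2": L2, "df": (df_num, df_den)},
    )
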