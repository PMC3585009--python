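"""Vectorized least-squares internals shared by the marker tests and the
test-statistic correlation matrix.

The per-pair model  y = b0 + b1*s1 + b2*s2 + b3*s1*s2 + C g + e  is fit for
all m1*m2 SNP pairs at once. Covariates (and the intercept) are projected out
of y, the dosages and the raw dosage products first (Frisch-Waugh), which
reduces every pair to a 3-parameter regression whose normal equations are
assembled with einsums and solved batched.
"""
from __future__ import annotations

from typing import Optional, Tuple

import numpy as np

COND_MAX = 1e12  # condition-number cutoff for X'X


def residualize(M: np.ndarray, covars: Optional[np.ndarray]) -> np.ndarray:
    """Residual of each column of ``M`` on [1, covars] via QR."""
    M = np.asarray(M, dtype=float)
    squeeze = M.ndim == 1
    if squeeze:
        M = M[:, None]
    n = M.shape[0]
    if covars is None or covars.size == 0:
        out = M - M.mean(axis=0)
    else:
        Z = np.column_stack([np.ones(n), covars])
        Q, _ = np.linalg.qr(Z)
        out = M - Q @ (Q.T @ M)
    return out[:, 0] if squeeze else out


class PairDesigns:
    """Batched design-matrix quantities for all m1*m2 interaction models.

    After residualizing on [1, covars], each pair (i, j) has the design
    ``[a1_i, a2_j, prod_ij]`` where ``prod_ij`` is the residualized raw
    product ``s1_i * s2_j``. This class precomputes the batched 3x3 normal
    matrices, their inverses, and the interaction-row residual vectors
    (the ``u`` vectors whose correlations form the Sigma matrix).
    """

    def __init__(
        self,
        G1: np.ndarray,
        G2: np.ndarray,
        covars: Optional[np.ndarray] = None,
    ) -> None:
        G1 = np.asarray(G1, dtype=float)
        G2 = np.asarray(G2, dtype=float)
        if G1.ndim == 1:
            G1 = G1[:, None]
        if G2.ndim == 1:
            G2 = G2[:, None]
        n, m1 = G1.shape
        m2 = G2.shape[1]
        if G2.shape[0] != n:
            raise ValueError("gene-1 and gene-2 genotypes have different sample sizes")
        self.n, self.m1, self.m2 = n, m1, m2
        self.n_covars = 0 if covars is None else np.atleast_2d(covars).shape[1]
        # 4 model params (intercept, s1, s2, product) + covariates
        self.df = n - (4 + self.n_covars)
        if n < 10 * (4 + self.n_covars):
            from .datatypes import SampleSizeError

            raise SampleSizeError(
                f"n={n} too small for {4 + self.n_covars} model parameters "
                f"(need n >= {10 * (4 + self.n_covars)})"
            )
        Praw = np.einsum("ni,nj->nij", G1, G2).reshape(n, m1 * m2)
        self.A1 = residualize(G1, covars)
        self.A2 = residualize(G2, covars)
        self.P = residualize(Praw, covars).reshape(n, m1, m2)

        A1, A2, P3 = self.A1, self.A2, self.P
        q = m1 * m2
        # normal-equation blocks, shape (m1, m2) each
        s11 = np.einsum("ni,ni->i", A1, A1)  # (m1,)
        s22 = np.einsum("nj,nj->j", A2, A2)  # (m2,)
        s12 = A1.T @ A2  # (m1, m2)
        s13 = np.einsum("ni,nij->ij", A1, P3)
        s23 = np.einsum("nj,nij->ij", A2, P3)
        s33 = np.einsum("nij,nij->ij", P3, P3)
        XtX = np.empty((m1, m2, 3, 3))
        XtX[..., 0, 0] = s11[:, None]
        XtX[..., 1, 1] = s22[None, :]
        XtX[..., 0, 1] = XtX[..., 1, 0] = s12
        XtX[..., 0, 2] = XtX[..., 2, 0] = s13
        XtX[..., 1, 2] = XtX[..., 2, 1] = s23
        XtX[..., 2, 2] = s33
        self.XtX = XtX.reshape(q, 3, 3)
        # flag ill-conditioned pairs instead of failing the whole batch
        with np.errstate(all="ignore"):
            cond = np.linalg.cond(self.XtX)
        self.singular = ~np.isfinite(cond) | (cond > COND_MAX)
        XtX_safe = self.XtX.copy()
        XtX_safe[self.singular] = np.eye(3)
        self.XtX_inv = np.linalg.inv(XtX_safe)

        # interaction-row residual u_ij = prod_ij - [a1_i, a2_j] @ gamma
        gamma = np.linalg.solve(
            self.XtX[:, :2, :2] + 1e-12 * np.eye(2),
            self.XtX[:, :2, 2:3],
        )[..., 0].reshape(m1, m2, 2)
        self.U = (
            P3
            - A1[:, :, None] * gamma[None, :, :, 0]
            - A2[:, None, :] * gamma[None, :, :, 1]
        ).reshape(n, q)


def batched_interaction_fit(
    designs: PairDesigns, y_resid: np.ndarray
) -> Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Product-term estimates for every pair given covariate-residualized y.

    Returns ``(b3, se_b3, t, p_two_sided)``, each of shape (m1*m2,).
    Ill-conditioned pairs come back as NaN (see ``designs.singular``).
    """
    from scipy import stats

    n, m1, m2 = designs.n, designs.m1, designs.m2
    q = m1 * m2
    A1, A2, P3 = designs.A1, designs.A2, designs.P
    y = np.asarray(y_resid, dtype=float).ravel()
    Xty = np.empty((q, 3))
    Xty[:, 0] = np.repeat(A1.T @ y, m2)
    Xty[:, 1] = np.tile(A2.T @ y, m1)
    Xty[:, 2] = np.einsum("nij,n->ij", P3, y).ravel()
    beta = np.einsum("qab,qb->qa", designs.XtX_inv, Xty)
    yty = float(y @ y)
    rss = yty - np.einsum("qa,qa->q", beta, Xty)
    rss = np.maximum(rss, 0.0)
    sigma2 = rss / designs.df
    se = np.sqrt(sigma2 * designs.XtX_inv[:, 2, 2])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta[:, 2] / se
    p = 2.0 * stats.t.sf(np.abs(t), designs.df)
    bad = designs.singular
    for arr in (t, p, se):
        arr[bad] = np.nan
    b3 = beta[:, 2].copy()
    b3[bad] = np.nan
    return b3, se, t, p
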