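"""Combining pairwise interaction P values into gene-level P values.

Four combiners are provided. Two are analytic:

* ``gg_minp`` — the minimum P value referred to the multivariate-normal
  rectangle probability Pr(|Z_i| < Phi^-1(1 - Pmin/2) for all i),
  Z ~ MVN(0, Sigma);

* ``gg_gates`` — the extended Simes procedure: with P values sorted
  ascending, min_j m_e * p_(j) / m_e(j), where m_e and m_e(j) are
  effective numbers of independent tests computed from Sigma by the
  Moskvina-Schmidt prefix-maximum rule
  m_e(j) = 1 + sum_{i=2..j} sqrt(1 - max_{l<i} rho_{il}^2).

Two are sampling-based, sharing an adaptive empirical-P engine:

* ``gg_tts`` — truncated tail strength, sum over p_(j) <= tau of
  (1 - p_(j) * (m+1)/j); larger is more significant;

* ``gg_tprod`` — truncated product, product of all p <= tau (evaluated in
  logs); smaller is more significant.

The null for the sampling methods is Z ~ MVN(0, Sigma) mapped to two-sided
P values (normal approximation of the t statistics, appropriate at GWAS
sample sizes). The adaptive scheme draws 1000 vectors, escalates by 99,000
when the running empirical P is < 0.01 and by a further 99,900,000 when it
is < 1e-4, for a ceiling of 1e8 draws and an empirical-P floor of 1e-8.
Ties count as extreme.
"""
from __future__ import annotations

import math
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np
from scipy.special import ndtri

from .correlation import SigmaMatrix, repair_psd
from .datatypes import GenePairResult, TruncationConfig
from .mvnorm import cholesky_factor, mvn_rectangle, sample_null_pvalues

__all__ = [
    "gg_minp",
    "gg_gates",
    "gg_tts",
    "gg_tprod",
    "tts_statistic",
    "tprod_statistic",
    "empirical_p",
    "effective_n_tests",
    "chunk_pairs",
]


def _check(p_values: np.ndarray, sigma: SigmaMatrix) -> np.ndarray:
    p = np.asarray(p_values, dtype=float).ravel()
    if p.size != sigma.q:
        raise ValueError(
            f"{p.size} P values but Sigma is {sigma.q}x{sigma.q}"
        )
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("P values must lie in (0, 1] and be finite")
    return p


def gg_minp(
    p_values: Sequence[float],
    sigma: SigmaMatrix,
    gene1: str = "gene1",
    gene2: str = "gene2",
    chunk_id: Optional[str] = None,
    seed: int = 0,
    n_qmc: int = 4096,
    n_shifts: int = 2,
) -> GenePairResult:
    """Minimum-P gene-level test via the MVN rectangle probability.

    The gene-level P is 1 - Pr(all |Z_i| below the two-sided critical value
    of Pmin), computed by seeded quasi-Monte-Carlo; the result is clamped to
    the rigorous envelope [Pmin, m*Pmin] (Bonferroni bounds), which also
    absorbs integration noise.
    """
    p = _check(p_values, sigma)
    pmin = float(p.min())
    m = p.size
    if m == 1:
        p_gene = pmin
    else:
        c = -ndtri(pmin / 2.0)  # = Phi^-1(1 - pmin/2)
        if not np.isfinite(c):
            p_gene = min(1.0, m * pmin)
        else:
            inside = mvn_rectangle(
                np.full(m, -c), np.full(m, c), sigma.values,
                seed=seed, n_qmc=n_qmc, n_shifts=n_shifts,
            )
            p_gene = float(np.clip(1.0 - inside, pmin, min(1.0, m * pmin)))
    return GenePairResult(
        gene1=gene1, gene2=gene2, method="minP",
        statistic=pmin, p_gene=p_gene, n_pairs=m,
        chunk_id=chunk_id, seed=seed,
    )


def effective_n_tests(sigma_ordered: np.ndarray) -> np.ndarray:
    """Moskvina-Schmidt effective test counts over growing prefixes.

    ``sigma_ordered`` is Sigma with rows/columns arranged in the testing
    order (ascending P value for GATES). Returns m_e(j) for j = 1..m;
    the last entry is the overall m_e.
    """
    R2 = np.asarray(sigma_ordered, dtype=float) ** 2
    m = R2.shape[0]
    w = np.empty(m)
    w[0] = 1.0
    for i in range(1, m):
        w[i] = math.sqrt(max(0.0, 1.0 - R2[i, :i].max()))
    return np.cumsum(w)


def gg_gates(
    p_values: Sequence[float],
    sigma: SigmaMatrix,
    gene1: str = "gene1",
    gene2: str = "gene2",
    chunk_id: Optional[str] = None,
) -> GenePairResult:
    """Extended Simes (GATES) gene-level test."""
    p = _check(p_values, sigma)
    order = np.argsort(p, kind="stable")
    ps = p[order]
    S = sigma.values[np.ix_(order, order)]
    me_j = effective_n_tests(S)
    me = me_j[-1]
    p_gene = float(min(1.0, np.min(me * ps / me_j)))
    return GenePairResult(
        gene1=gene1, gene2=gene2, method="GATES",
        statistic=p_gene, p_gene=p_gene, n_pairs=p.size, chunk_id=chunk_id,
    )


def tts_statistic(p_values: Sequence[float], tau: float = 0.05) -> float:
    """Truncated tail strength: sum over sorted p_(j) <= tau of
    1 - p_(j)*(m+1)/j. Zero when nothing passes the cutoff; larger is more
    significant. (The constant 1/m prefactor of the original tail strength
    is dropped — empirical-P ranking is invariant to it — so statistics are
    comparable across runs only at equal m.)
    """
    if not 0 < tau < 1:
        raise ValueError("tau must lie in (0, 1)")
    p = np.sort(np.asarray(p_values, dtype=float).ravel())
    m = p.size
    j = np.arange(1, m + 1)
    mask = p <= tau
    return float(np.sum((1.0 - p * (m + 1) / j)[mask]))


def _tts_from_sparse(rows: np.ndarray, vals: np.ndarray, B: int, m: int) -> np.ndarray:
    """tTS statistic per draw from the sparse (draw index, P value) pairs of
    entries that passed truncation.

    Because every non-contributing entry is larger than tau, the ascending
    ranks of contributing entries within the full row equal their ranks
    among themselves — so only the truncated set needs sorting. Draws with
    no qualifying entries score 0.
    """
    if rows.size == 0:
        return np.zeros(B)
    order = np.lexsort((vals, rows))
    rows_s = rows[order]
    vals_s = vals[order]
    counts = np.bincount(rows_s, minlength=B)
    starts = np.concatenate([[0], np.cumsum(counts)[:-1]])
    rank = np.arange(rows_s.size) - starts[rows_s] + 1
    contrib = 1.0 - vals_s * (m + 1) / rank
    return np.bincount(rows_s, weights=contrib, minlength=B)


def _tts_batch(P: np.ndarray, tau: float) -> np.ndarray:
    """tTS statistic per row of an (B, m) matrix of P values."""
    B, m = P.shape
    rows, cols = np.nonzero(P <= tau)
    return _tts_from_sparse(rows, P[rows, cols], B, m)


def tprod_statistic(p_values: Sequence[float], tau: float = 0.05) -> float:
    """Truncated product: product of all p <= tau (1 for the empty set);
    smaller is more significant."""
    if not 0 < tau < 1:
        raise ValueError("tau must lie in (0, 1)")
    return float(math.exp(log_tprod_statistic(p_values, tau)))


def log_tprod_statistic(p_values: Sequence[float], tau: float = 0.05) -> float:
    """log of the truncated product; avoids underflow for many small P."""
    p = np.asarray(p_values, dtype=float).ravel()
    mask = p <= tau
    if not mask.any():
        return 0.0
    return float(np.log(p[mask]).sum())


def _log_tprod_batch(P: np.ndarray, tau: float) -> np.ndarray:
    B = P.shape[0]
    rows, cols = np.nonzero(P <= tau)
    if rows.size == 0:
        return np.zeros(B)
    logs = np.log(np.maximum(P[rows, cols], 1e-320))
    return np.bincount(rows, weights=logs, minlength=B)


def _adaptive_truncated_sampling(
    p_values: np.ndarray,
    sigma_values: np.ndarray,
    tau: float,
    stages: Sequence[int],
    thresholds: Sequence[float],
    seed: int,
    want_tts: bool = True,
    want_tprod: bool = True,
    batch_size: int = 1 << 16,
) -> Tuple[float, float, int]:
    """Shared adaptive null-sampling engine for tTS and tProd.

    Draws correlated null z-vectors in batches and converts only entries
    with |z| above the two-sided tau quantile to P values — no other entry
    can enter either truncated statistic — which keeps the escalated stages
    cheap. Returns ``(p_tts, p_tprod, n_draws)``; ties count as extreme and
    the estimate is floored at 1/n_draws.
    """
    p = np.asarray(p_values, dtype=float).ravel()
    m = p.size
    chol = cholesky_factor(sigma_values)
    rng = np.random.default_rng(seed)
    obs_tts = tts_statistic(p, tau) if want_tts else None
    obs_ltp = log_tprod_statistic(p, tau) if want_tprod else None
    c_tau = -ndtri(tau / 2.0)
    ext_tts = ext_tp = 0
    total = 0
    p_tts = p_tp = 1.0
    from scipy.special import ndtr

    for k, stage in enumerate(stages):
        remaining = int(stage)
        while remaining > 0:
            b = min(remaining, batch_size)
            Z = rng.standard_normal((b, m)) @ chol.T
            np.abs(Z, out=Z)
            rows, cols = np.nonzero(Z >= c_tau)
            if rows.size:
                vals = 2.0 * ndtr(-Z[rows, cols])
                if want_tts:
                    stats_tts = _tts_from_sparse(rows, vals, b, m)
                    ext_tts += int(np.count_nonzero(stats_tts >= obs_tts))
                if want_tprod:
                    logs = np.log(np.maximum(vals, 1e-320))
                    stats_ltp = np.bincount(rows, weights=logs, minlength=b)
                    ext_tp += int(np.count_nonzero(stats_ltp <= obs_ltp))
            else:
                if want_tts and obs_tts is not None and obs_tts <= 0:
                    ext_tts += b
                if want_tprod and obs_ltp is not None and obs_ltp >= 0:
                    ext_tp += b
            total += b
            remaining -= b
        if want_tts:
            p_tts = max(ext_tts, 1) / total
        if want_tprod:
            p_tp = max(ext_tp, 1) / total
        running = min(p_tts if want_tts else 1.0, p_tp if want_tprod else 1.0)
        if k < len(thresholds) and running >= thresholds[k]:
            break
    return p_tts, p_tp, total


def empirical_p(
    observed: float,
    statistic_fn: Callable[[np.ndarray], np.ndarray],
    sigma: SigmaMatrix,
    config: TruncationConfig = None,
    seed: int = 0,
    larger_is_significant: bool = True,
    batch_size: int = 1 << 16,
) -> Tuple[float, int]:
    """Adaptive empirical P value of a statistic of correlated null P values.

    ``statistic_fn`` maps an (B, m) matrix of two-sided P values to B
    statistic values. Draws escalate through ``config.stages`` while the
    running empirical P stays below the stage thresholds. Returns
    ``(p_emp, n_draws)`` with the tie-inclusive estimator
    p = max(count_extreme, 1) / n_draws, whose floor at the default ceiling
    of 1e8 draws is 1e-8.
    """
    if config is None:
        config = TruncationConfig()
    if not np.isfinite(observed):
        raise ValueError("observed statistic is not finite")
    chol = cholesky_factor(repair_psd(sigma).values)
    rng = np.random.default_rng(seed)
    extreme = 0
    total = 0
    for stage_idx, stage in enumerate(config.stages):
        remaining = int(stage)
        while remaining > 0:
            b = min(remaining, batch_size)
            P = sample_null_pvalues(chol, b, rng)
            stats = statistic_fn(P)
            if larger_is_significant:
                extreme += int(np.count_nonzero(stats >= observed))
            else:
                extreme += int(np.count_nonzero(stats <= observed))
            total += b
            remaining -= b
        p_emp = max(extreme, 1) / total
        if stage_idx < len(config.thresholds) and p_emp >= config.thresholds[stage_idx]:
            break
    return p_emp, total


def gg_tts(
    p_values: Sequence[float],
    sigma: SigmaMatrix,
    config: TruncationConfig = None,
    gene1: str = "gene1",
    gene2: str = "gene2",
    chunk_id: Optional[str] = None,
    seed: int = 0,
) -> GenePairResult:
    """Truncated tail-strength gene-level test with sampled empirical P."""
    if config is None:
        config = TruncationConfig()
    p = _check(p_values, sigma)
    obs = tts_statistic(p, config.tau)
    p_emp, _, n_draws = _adaptive_truncated_sampling(
        p, repair_psd(sigma).values, config.tau, config.stages,
        config.thresholds, seed, want_tts=True, want_tprod=False,
    )
    return GenePairResult(
        gene1=gene1, gene2=gene2, method="tTS",
        statistic=obs, p_gene=p_emp, n_pairs=p.size,
        chunk_id=chunk_id, n_null_samples=n_draws, seed=seed,
    )


def gg_tprod(
    p_values: Sequence[float],
    sigma: SigmaMatrix,
    config: TruncationConfig = None,
    gene1: str = "gene1",
    gene2: str = "gene2",
    chunk_id: Optional[str] = None,
    seed: int = 0,
) -> GenePairResult:
    """Truncated-product gene-level test with sampled empirical P."""
    if config is None:
        config = TruncationConfig()
    p = _check(p_values, sigma)
    log_obs = log_tprod_statistic(p, config.tau)
    _, p_emp, n_draws = _adaptive_truncated_sampling(
        p, repair_psd(sigma).values, config.tau, config.stages,
        config.thresholds, seed, want_tts=False, want_tprod=True,
    )
    return GenePairResult(
        gene1=gene1, gene2=gene2, method="tProd",
        statistic=float(math.exp(log_obs)), p_gene=p_emp, n_pairs=p.size,
        chunk_id=chunk_id, n_null_samples=n_draws, seed=seed,
    )


def chunk_pairs(m1: int, m2: int, max_pairs: int = 500) -> List[Tuple[range, range]]:
    """Partition the m1 x m2 pair grid into contiguous blocks of <= max_pairs.

    Blocks are products of contiguous gene-1 and gene-2 SNP ranges, in
    genomic order, so within-chunk LD (and hence the information in Sigma)
    stays high. Each chunk is analyzed as its own gene-level test and
    counts separately toward multiple-testing correction.
    """
    if m1 < 1 or m2 < 1 or max_pairs < 1:
        raise ValueError("m1, m2 and max_pairs must be positive")
    if m1 * m2 <= max_pairs:
        return [(range(m1), range(m2))]
    # block side lengths: keep gene-2 blocks <= max_pairs, then tile gene 1
    b2 = min(m2, max_pairs)
    b1 = max(1, max_pairs // b2)
    chunks = []
    for i0 in range(0, m1, b1):
        for j0 in range(0, m2, b2):
            chunks.append((range(i0, min(i0 + b1, m1)), range(j0, min(j0 + b2, m2))))
    return chunks
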