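"""Synthetic genotypes, phenotypes, and the type-I-error / power harness.

Real cohort haplotypes are emulated by a Gaussian-copula haplotype pool:
for each locus, latent normals with an autoregressive correlation profile
rho_latent = 0.8^|i-j| are thresholded at the per-SNP allele-frequency
quantile, giving LD that decays with marker distance; 20,000 haplotypes are
paired into 10,000 diploid individuals, and every replicate draws its n
individuals from that pool without replacement. The two loci are generated
independently (linkage equilibrium between genes).

The default two loci carry 53 and 28 SNPs with 14 and 10 tag SNPs; only the
tags are tested, so causal SNPs can be Observed (a tag) or Untyped. The
causal-SNP allele frequencies are fixed targets; remaining frequencies are
a fixed, reproducible draw from U(0.10, 0.50).

Phenotypes follow the linear interaction model: under the null y is pure
standard-normal noise; under the alternative
y = sum over causal pairs of (b1*Sa + b2*Sb + b3*Sa*Sb) + e, e ~ N(0,1),
with b1 = b2 = b3 by default.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import ndtr, ndtri

from ._core import PairDesigns, batched_interaction_fit
from .combine import _adaptive_truncated_sampling, effective_n_tests
from .correlation import corr_products_external, sigma_from_external_ld
from .datatypes import GenotypeMatrix, PhenotypeVector
from .mvnorm import mvn_rectangle
from .pca_test import gg_pc_test

__all__ = [
    "LocusModel",
    "ScenarioSpec",
    "SimulationReport",
    "HaplotypePool",
    "build_pool",
    "simulate_genotypes",
    "simulate_phenotype",
    "run_type1",
    "run_power",
    "calibrate_polynomial",
    "default_scenario",
    "DEFAULT_LOCUS1",
    "DEFAULT_LOCUS2",
]

ALL_METHODS = ("PC", "minP", "GATES", "tTS", "tProd")


@dataclass
class LocusModel:
    """One locus: SNP count, per-SNP allele-frequency targets, tag subset.

    ``tags`` are 1-based SNP indices (matching how simulation scenarios
    label SNPs, e.g. pair "30-15").
    """

    n_snps: int
    maf: np.ndarray
    tags: Tuple[int, ...]
    latent_rho: float = 0.8

    def __post_init__(self) -> None:
        self.maf = np.asarray(self.maf, dtype=float)
        if self.maf.size != self.n_snps:
            raise ValueError("maf vector length != n_snps")
        if np.any((self.maf <= 0) | (self.maf > 0.5)):
            raise ValueError("MAF targets must lie in (0, 0.5]")
        if any(not 1 <= t <= self.n_snps for t in self.tags):
            raise ValueError("tag index out of range")

    @property
    def tag_idx0(self) -> np.ndarray:
        return np.asarray(self.tags, dtype=int) - 1


def _default_maf(n_snps: int, fixed: Dict[int, float], seed: int) -> np.ndarray:
    """Causal-SNP frequencies are fixed targets; the rest are a frozen draw."""
    rng = np.random.default_rng(seed)
    maf = rng.uniform(0.10, 0.50, size=n_snps)
    for idx1, f in fixed.items():
        maf[idx1 - 1] = f
    return maf


# Causal-SNP MAF targets used across the standard scenarios (1-based index).
_LOCUS1_FIXED = {6: 0.12, 10: 0.10, 19: 0.32, 20: 0.10, 29: 0.10,
                 30: 0.45, 39: 0.41, 40: 0.41, 47: 0.29, 48: 0.30}
_LOCUS2_FIXED = {4: 0.49, 5: 0.39, 9: 0.47, 10: 0.44, 15: 0.48,
                 17: 0.39, 20: 0.34, 22: 0.38, 25: 0.44, 27: 0.43}

# Tag subsets: every Observed causal SNP is a tag, every Untyped one is not.
# Spacing is mixed (some adjacent tags) as in real block-structured tag sets,
# so tags retain moderate mutual LD.
DEFAULT_LOCUS1 = LocusModel(
    n_snps=53,
    maf=_default_maf(53, _LOCUS1_FIXED, seed=53),
    tags=(2, 5, 6, 13, 18, 19, 28, 29, 34, 38, 39, 46, 47, 52),
)
DEFAULT_LOCUS2 = LocusModel(
    n_snps=28,
    maf=_default_maf(28, _LOCUS2_FIXED, seed=28),
    tags=(3, 4, 8, 9, 13, 16, 17, 22, 25, 26),
)


@dataclass
class ScenarioSpec:
    """One simulation scenario (null when ``causal_pairs`` is empty)."""

    locus1: LocusModel = field(default_factory=lambda: DEFAULT_LOCUS1)
    locus2: LocusModel = field(default_factory=lambda: DEFAULT_LOCUS2)
    causal_pairs: Tuple[Tuple[int, int], ...] = ()  # 1-based (locus1, locus2)
    effect_size: float = 0.0  # b3, shared across pairs
    b_main: Optional[float] = None  # b1 = b2; defaults to effect_size
    maf_targets: Tuple[Tuple[float, float], ...] = ()  # optional per-pair overrides
    n: int = 1000
    replicates: int = 2000
    alpha: float = 0.05
    seed: int = 0
    methods: Tuple[str, ...] = ALL_METHODS
    ld_source: str = "genotypes"  # or "external"
    tau: float = 0.05
    stages: Tuple[int, ...] = (1_000, 99_000)
    thresholds: Tuple[float, ...] = (0.01,)
    pool_haplotypes: int = 20_000
    minp_qmc: int = 512
    minp_shifts: int = 1

    def __post_init__(self) -> None:
        for i, j in self.causal_pairs:
            if not (1 <= i <= self.locus1.n_snps and 1 <= j <= self.locus2.n_snps):
                raise ValueError(f"causal pair ({i}, {j}) outside the loci")
        if self.ld_source not in ("genotypes", "external"):
            raise ValueError("ld_source must be 'genotypes' or 'external'")
        unknown = set(self.methods) - set(ALL_METHODS)
        if unknown:
            raise ValueError(f"unknown methods: {sorted(unknown)}")
        if self.maf_targets:
            if len(self.maf_targets) != len(self.causal_pairs):
                raise ValueError("maf_targets must match causal_pairs")
            for (i, j), (f1, f2) in zip(self.causal_pairs, self.maf_targets):
                self.locus1.maf[i - 1] = f1
                self.locus2.maf[j - 1] = f2

    def causal_status(self) -> List[Tuple[str, str]]:
        """U/O status per causal pair, derived from tag membership."""
        t1, t2 = set(self.locus1.tags), set(self.locus2.tags)
        return [
            ("O" if i in t1 else "U", "O" if j in t2 else "U")
            for i, j in self.causal_pairs
        ]


@dataclass
class SimulationReport:
    """Rejection proportions per method with Monte-Carlo standard errors."""

    rejections: Dict[str, int]
    replicates: int
    alpha: float
    scenario: Optional[ScenarioSpec] = None

    @property
    def rates(self) -> Dict[str, float]:
        return {m: r / self.replicates for m, r in self.rejections.items()}

    @property
    def mcse(self) -> Dict[str, float]:
        out = {}
        for m, r in self.rejections.items():
            p = r / self.replicates
            out[m] = float(np.sqrt(p * (1 - p) / self.replicates))
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "method": list(self.rejections),
                "rejection_rate": [self.rates[m] for m in self.rejections],
                "mcse": [self.mcse[m] for m in self.rejections],
                "replicates": self.replicates,
                "alpha": self.alpha,
            }
        )


@dataclass
class HaplotypePool:
    """Diploid dosage pool for one locus (individuals x SNPs)."""

    dosages: np.ndarray
    maf_target: np.ndarray

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    def realized_maf(self) -> np.ndarray:
        return self.dosages.mean(axis=0) / 2.0

    def ld_matrix(self) -> np.ndarray:
        return np.corrcoef(self.dosages.T)


def build_pool(locus: LocusModel, n_haplotypes: int = 20_000, seed: int = 0) -> HaplotypePool:
    """Gaussian-copula haplotype pool, paired into diploid individuals."""
    if n_haplotypes % 2:
        raise ValueError("n_haplotypes must be even")
    m = locus.n_snps
    idx = np.arange(m)
    R = locus.latent_rho ** np.abs(idx[:, None] - idx[None, :])
    L = np.linalg.cholesky(R)
    rng = np.random.default_rng(seed)
    Z = rng.standard_normal((n_haplotypes, m)) @ L.T
    alleles = (Z < ndtri(locus.maf)).astype(np.int8)
    dosages = (alleles[0::2] + alleles[1::2]).astype(float)
    sd = dosages.std(axis=0)
    if np.any(sd == 0):
        raise ValueError(
            "monomorphic SNP in the generated pool; MAF target too extreme "
            "for this pool size"
        )
    return HaplotypePool(dosages=dosages, maf_target=locus.maf.copy())


def simulate_genotypes(
    spec: ScenarioSpec, seed: Optional[int] = None
) -> Tuple[GenotypeMatrix, GenotypeMatrix]:
    """Draw one sample of n individuals (full loci, all SNPs)."""
    ss = np.random.SeedSequence(spec.seed if seed is None else seed)
    s_pool1, s_pool2, s_draw = ss.spawn(3)
    pool1 = build_pool(spec.locus1, spec.pool_haplotypes, seed=s_pool1)
    pool2 = build_pool(spec.locus2, spec.pool_haplotypes, seed=s_pool2)
    rng = np.random.default_rng(s_draw)
    idx = rng.choice(pool1.n_individuals, size=spec.n, replace=False)
    g1 = GenotypeMatrix(
        dosages=pool1.dosages[idx],
        snp_ids=[f"l1s{k + 1}" for k in range(spec.locus1.n_snps)],
    )
    g2 = GenotypeMatrix(
        dosages=pool2.dosages[idx],
        snp_ids=[f"l2s{k + 1}" for k in range(spec.locus2.n_snps)],
    )
    return g1, g2


def simulate_phenotype(
    genos: Tuple[GenotypeMatrix, GenotypeMatrix],
    spec: ScenarioSpec,
    seed: int = 0,
) -> PhenotypeVector:
    """Phenotype under the scenario's interaction model (noise-only if null)."""
    rng = np.random.default_rng(seed)
    g1, g2 = genos
    y = rng.standard_normal(g1.n_samples)
    y += _genetic_values(g1.dosages, g2.dosages, spec)
    return PhenotypeVector(values=y, trait_name="simulated")


def _genetic_values(D1: np.ndarray, D2: np.ndarray, spec: ScenarioSpec) -> np.ndarray:
    if not spec.causal_pairs:
        return 0.0
    b3 = spec.effect_size
    b1 = b2 = spec.b_main if spec.b_main is not None else b3
    g = np.zeros(D1.shape[0])
    for i, j in spec.causal_pairs:
        sa = D1[:, i - 1]
        sb = D2[:, j - 1]
        g += b1 * sa + b2 * sb + b3 * sa * sb
    return g


def _sigma_from_designs(designs: PairDesigns) -> np.ndarray:
    U = designs.U
    norms = np.linalg.norm(U, axis=0)
    norms[norms == 0] = 1.0
    Un = U / norms
    S = np.clip(Un.T @ Un, -1.0, 1.0)
    np.fill_diagonal(S, 1.0)
    return S


def _gates_p(p: np.ndarray, S: np.ndarray) -> float:
    order = np.argsort(p, kind="stable")
    ps = p[order]
    me_j = effective_n_tests(S[np.ix_(order, order)])
    return float(min(1.0, np.min(me_j[-1] * ps / me_j)))


def _minp_p(p: np.ndarray, S: np.ndarray, seed: int, n_qmc: int, n_shifts: int) -> float:
    pmin = float(p.min())
    m = p.size
    c = -ndtri(pmin / 2.0)
    if not np.isfinite(c):
        return min(1.0, m * pmin)
    inside = mvn_rectangle(
        np.full(m, -c), np.full(m, c), S, seed=seed, n_qmc=n_qmc, n_shifts=n_shifts
    )
    return float(np.clip(1.0 - inside, pmin, min(1.0, m * pmin)))


def _sampling_ps(
    p: np.ndarray,
    S: np.ndarray,
    tau: float,
    stages: Sequence[int],
    thresholds: Sequence[float],
    seed: int,
    want_tts: bool,
    want_tprod: bool,
) -> Tuple[float, float]:
    """Empirical P for tTS and tProd from one shared stream of null draws."""
    p_tts, p_tp, _ = _adaptive_truncated_sampling(
        p, S, tau, stages, thresholds, seed,
        want_tts=want_tts, want_tprod=want_tprod,
    )
    return p_tts, p_tp


def _external_sigma(spec: ScenarioSpec, ref_seed_pair) -> np.ndarray:
    """Sigma for the tag pairs from an independent reference pool's LD."""
    ref1 = build_pool(spec.locus1, spec.pool_haplotypes, seed=ref_seed_pair[0])
    ref2 = build_pool(spec.locus2, spec.pool_haplotypes, seed=ref_seed_pair[1])
    t1, t2 = spec.locus1.tag_idx0, spec.locus2.tag_idx0
    ld1 = np.corrcoef(ref1.dosages[:, t1].T)
    ld2 = np.corrcoef(ref2.dosages[:, t2].T)
    f1 = ref1.realized_maf()[t1]
    f2 = ref2.realized_maf()[t2]
    return sigma_from_external_ld(ld1, ld2, f1, f2).values


def _run_replicates(spec: ScenarioSpec, null: bool) -> SimulationReport:
    ss = np.random.SeedSequence(spec.seed)
    s_pool1, s_pool2, s_ref1, s_ref2, s_loop = ss.spawn(5)
    pool1 = build_pool(spec.locus1, spec.pool_haplotypes, seed=s_pool1)
    pool2 = build_pool(spec.locus2, spec.pool_haplotypes, seed=s_pool2)
    t1, t2 = spec.locus1.tag_idx0, spec.locus2.tag_idx0
    sigma_ext = (
        _external_sigma(spec, (s_ref1, s_ref2))
        if spec.ld_source == "external"
        else None
    )
    rng = np.random.default_rng(s_loop)
    rej = {m: 0 for m in spec.methods}
    want_tts = "tTS" in spec.methods
    want_tprod = "tProd" in spec.methods
    snp1_ids = [f"l1s{k + 1}" for k in t1]
    snp2_ids = [f"l2s{k + 1}" for k in t2]
    for _ in range(spec.replicates):
        idx = rng.choice(pool1.n_individuals, size=spec.n, replace=False)
        D1full = pool1.dosages[idx]
        D2full = pool2.dosages[idx]
        D1, D2 = D1full[:, t1], D2full[:, t2]
        y = rng.standard_normal(spec.n)
        if not null:
            y = y + _genetic_values(D1full, D2full, spec)
        yr = y - y.mean()
        designs = PairDesigns(D1, D2, None)
        p = batched_interaction_fit(designs, yr)[3]
        ok = np.isfinite(p)
        S = sigma_ext if sigma_ext is not None else _sigma_from_designs(designs)
        if not ok.all():
            keep = np.flatnonzero(ok)
            p = p[keep]
            S = S[np.ix_(keep, keep)]
        rep_seed = int(rng.integers(0, 2**31 - 1))
        if "minP" in spec.methods:
            pg = _minp_p(p, S, rep_seed, spec.minp_qmc, spec.minp_shifts)
            rej["minP"] += pg < spec.alpha
        if "GATES" in spec.methods:
            rej["GATES"] += _gates_p(p, S) < spec.alpha
        if want_tts or want_tprod:
            p_tts, p_tp = _sampling_ps(
                p, S, spec.tau, spec.stages, spec.thresholds, rep_seed,
                want_tts, want_tprod,
            )
            if want_tts:
                rej["tTS"] += p_tts < spec.alpha
            if want_tprod:
                rej["tProd"] += p_tp < spec.alpha
        if "PC" in spec.methods:
            g1 = GenotypeMatrix(dosages=D1, snp_ids=snp1_ids)
            g2 = GenotypeMatrix(dosages=D2, snp_ids=snp2_ids)
            res = gg_pc_test(PhenotypeVector(values=y), g1, g2)
            rej["PC"] += res.p_gene < spec.alpha
    return SimulationReport(
        rejections=rej, replicates=spec.replicates, alpha=spec.alpha, scenario=spec
    )


def run_type1(spec: ScenarioSpec) -> SimulationReport:
    """Type-I error study: phenotype is pure noise regardless of causal pairs."""
    return _run_replicates(spec, null=True)


def run_power(spec: ScenarioSpec) -> SimulationReport:
    """Power study under the scenario's causal interaction pairs."""
    if not spec.causal_pairs or spec.effect_size == 0:
        return _run_replicates(spec, null=True)
    return _run_replicates(spec, null=False)


def default_scenario(**kwargs) -> ScenarioSpec:
    """The standard two-locus scenario with fresh locus copies."""
    kwargs.setdefault("locus1", replace(DEFAULT_LOCUS1, maf=DEFAULT_LOCUS1.maf.copy()))
    kwargs.setdefault("locus2", replace(DEFAULT_LOCUS2, maf=DEFAULT_LOCUS2.maf.copy()))
    return ScenarioSpec(**kwargs)


# ---------------------------------------------------------------------------
# polynomial calibration: product correlation -> test-statistic correlation
# ---------------------------------------------------------------------------


def latent_rho_for_allele_corr(f1: float, f2: float, target_r: float) -> float:
    """Latent-normal correlation giving allele-level correlation ``target_r``
    after thresholding at the quantiles of f1 and f2.

    Raises when the target is unattainable for the given frequencies (the
    Frechet bounds of correlated Bernoullis).
    """
    if target_r == 0:
        return 0.0
    t1, t2 = ndtri(f1), ndtri(f2)
    denom = np.sqrt(f1 * (1 - f1) * f2 * (1 - f2))

    def allele_r(rho: float) -> float:
        p11 = stats.multivariate_normal.cdf([t1, t2], cov=[[1, rho], [rho, 1]])
        return (p11 - f1 * f2) / denom

    lo, hi = -0.99999, 0.99999
    r_lo, r_hi = allele_r(lo), allele_r(hi)
    if not (r_lo - 1e-9 <= target_r <= r_hi + 1e-9):
        raise ValueError(
            f"allele correlation {target_r} unattainable for frequencies "
            f"({f1}, {f2}); attainable range is [{r_lo:.3f}, {r_hi:.3f}]"
        )
    return float(optimize.brentq(lambda r: allele_r(r) - target_r, lo, hi, xtol=1e-8))


def _hwe_pair_dosages(
    f1: float, f2: float, rho_latent: float, n: int, rng: np.random.Generator
) -> np.ndarray:
    """n individuals x 2 SNPs: two haplotypes per individual from the copula."""
    L = np.linalg.cholesky(np.array([[1.0, rho_latent], [rho_latent, 1.0]]))
    Z = rng.standard_normal((2 * n, 2)) @ L.T
    alleles = (Z < ndtri(np.array([f1, f2]))).astype(float)
    return alleles[0::2] + alleles[1::2]


def _null_t_stats(s1: np.ndarray, s2: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Interaction t statistic for each column of phenotype matrix Y."""
    n = s1.size
    X = np.column_stack([np.ones(n), s1, s2, s1 * s2])
    Q, _ = np.linalg.qr(X)
    QtY = Q.T @ Y
    rss = np.einsum("nr,nr->r", Y, Y) - np.einsum("kr,kr->r", QtY, QtY)
    sigma2 = rss / (n - 4)
    u = X[:, 3] - Q[:, :3] @ (Q[:, :3].T @ X[:, 3])
    uu = float(u @ u)
    b3 = (u @ Y) / uu
    return b3 / np.sqrt(sigma2 / uu)


@dataclass
class QuadrupleConfig:
    """One calibration point: within-gene correlations and frequencies."""

    r1: float
    r2: float
    f: Tuple[float, float, float, float]


def default_calibration_grid() -> List[QuadrupleConfig]:
    """Configurations spanning |r| in [0.1, 0.95] and f in [0.05, 0.5].

    Within-gene frequency pairs are kept equal so that high correlations
    remain attainable for thresholded genotypes. Only sign-consistent
    (positive within-gene LD) configurations are fitted: when r1 and r2
    have opposite signs — or are both negative at nonzero allele-frequency
    means — the mean-driven terms of the product covariance cancel against
    the LD-driven term, the product correlation collapses toward zero while
    the statistic correlation does not, and no function of the product
    correlation can recover it. That regime lies outside the polynomial's
    [0, 1] domain; with individual-level genotypes available the exact
    route should be used instead.
    """
    grid: List[QuadrupleConfig] = []
    rs = (0.1, 0.25, 0.4, 0.55, 0.7, 0.85, 0.95)
    f_pairs = ((0.05, 0.3), (0.2, 0.35), (0.35, 0.2), (0.5, 0.5), (0.1, 0.45))
    for r in rs:
        for fa, fb in f_pairs:
            grid.append(QuadrupleConfig(r, r, (fa, fa, fb, fb)))
        grid.append(QuadrupleConfig(r, max(0.1, r - 0.3), (0.25, 0.25, 0.4, 0.4)))
    return grid


def calibrate_polynomial(
    configs: Optional[List[QuadrupleConfig]] = None,
    n: int = 1000,
    reps: int = 2000,
    seed: int = 0,
    degree: int = 5,
) -> dict:
    """Refit the product-correlation -> statistic-correlation polynomial.

    For each configuration, four HWE dosage columns are generated (two per
    gene at the requested within-gene correlation), the product correlation
    is computed from the closed-form moment identity using realized LD and
    frequencies, and the statistic correlation is estimated empirically from
    ``reps`` null-phenotype interaction t-statistic pairs. A zero-intercept
    polynomial of the requested degree is then fit on magnitudes by least
    squares.

    Returns a dict with ``x`` (product correlations), ``y`` (statistic
    correlations), ``coefficients`` (x^1..x^degree) and ``r_squared``
    (centered R^2).
    """
    if configs is None:
        configs = default_calibration_grid()
    rng = np.random.default_rng(seed)
    xs, ys = [], []
    for cfg in configs:
        f1a, f1b, f2a, f2b = cfg.f
        rho1 = latent_rho_for_allele_corr(f1a, f1b, cfg.r1)
        rho2 = latent_rho_for_allele_corr(f2a, f2b, cfg.r2)
        G1 = _hwe_pair_dosages(f1a, f1b, rho1, n, rng)
        G2 = _hwe_pair_dosages(f2a, f2b, rho2, n, rng)
        if np.any(G1.std(axis=0) == 0) or np.any(G2.std(axis=0) == 0):
            continue
        r1_hat = float(np.corrcoef(G1.T)[0, 1])
        r2_hat = float(np.corrcoef(G2.T)[0, 1])
        f_hat = np.concatenate([G1.mean(axis=0) / 2, G2.mean(axis=0) / 2])
        x = corr_products_external(r1_hat, r2_hat, f_hat)
        Y = rng.standard_normal((n, reps))
        t11 = _null_t_stats(G1[:, 0], G2[:, 0], Y)
        t22 = _null_t_stats(G1[:, 1], G2[:, 1], Y)
        y_corr = float(np.corrcoef(t11, t22)[0, 1])
        xs.append(x)
        ys.append(y_corr)
    x_arr = np.abs(np.asarray(xs))
    y_arr = np.abs(np.asarray(ys))
    powers = np.stack([x_arr ** k for k in range(1, degree + 1)], axis=1)
    coeffs, *_ = np.linalg.lstsq(powers, y_arr, rcond=None)
    fitted = powers @ coeffs
    ss_res = float(np.sum((y_arr - fitted) ** 2))
    ss_tot = float(np.sum((y_arr - y_arr.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    return {
        "x": np.asarray(xs),
        "y": np.asarray(ys),
        "coefficients": coeffs,
        "r_squared": r2,
        "n": n,
        "reps": reps,
    }
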