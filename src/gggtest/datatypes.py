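"""Core containers for gene-based gene-gene interaction testing.

Dosage data, phenotypes, covariates and per-test results are kept in small
validated dataclasses; heavy numerics live in :mod:`gggtest.marker`,
:mod:`gggtest.correlation` and :mod:`gggtest.combine`.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "PhenotypeVector",
    "CovariateTable",
    "PairTestResult",
    "GenePairResult",
    "TruncationConfig",
    "GeneModel",
    "CollinearityError",
    "SampleSizeError",
]


class CollinearityError(ValueError):
    """Design matrix numerically singular (condition number of X'X > 1e12)."""


class SampleSizeError(ValueError):
    """Too few individuals for the number of model parameters."""


@dataclass
class GenotypeMatrix:
    """Additive dosages for ``n`` individuals at ``m`` SNPs.

    Dosages count copies of the reference allele and lie in [0, 2]
    (imputed data may be fractional). Monomorphic columns are rejected:
    a constant dosage carries no information and breaks every downstream
    design matrix.
    """

    dosages: np.ndarray  # n x m, float
    snp_ids: Sequence[str]
    positions: Optional[Sequence[tuple]] = None  # m tuples of (chrom, bp)
    ref_allele_freq: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D (individuals x SNPs) array")
        if not np.all(np.isfinite(self.dosages)):
            raise ValueError("dosages must be finite (impute missing values first)")
        if self.dosages.min() < -1e-9 or self.dosages.max() > 2 + 1e-9:
            raise ValueError("dosages must lie in [0, 2]")
        if len(self.snp_ids) != self.dosages.shape[1]:
            raise ValueError("snp_ids length does not match dosage columns")
        sd = self.dosages.std(axis=0)
        if np.any(sd == 0):
            bad = [self.snp_ids[i] for i in np.flatnonzero(sd == 0)]
            raise ValueError(f"monomorphic SNP column(s): {bad}")
        if self.positions is not None and len(self.positions) != self.n_snps:
            raise ValueError("positions length does not match dosage columns")
        if self.ref_allele_freq is None:
            self.ref_allele_freq = self.dosages.mean(axis=0) / 2.0
        else:
            self.ref_allele_freq = np.asarray(self.ref_allele_freq, dtype=float)
            if np.any((self.ref_allele_freq <= 0) | (self.ref_allele_freq >= 1)):
                raise ValueError("ref_allele_freq must lie in (0, 1)")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def select(self, indices: Sequence[int]) -> "GenotypeMatrix":
        """Sub-matrix restricted to the given SNP column indices."""
        idx = np.asarray(indices, dtype=int)
        return GenotypeMatrix(
            dosages=self.dosages[:, idx],
            snp_ids=[self.snp_ids[i] for i in idx],
            positions=None if self.positions is None else [self.positions[i] for i in idx],
            ref_allele_freq=self.ref_allele_freq[idx],
        )


@dataclass
class PhenotypeVector:
    """A quantitative trait, one finite value per individual."""

    values: np.ndarray
    trait_name: str = "trait"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if not np.all(np.isfinite(self.values)):
            raise ValueError("phenotype contains non-finite values")
        if self.values.var() == 0:
            raise ValueError("phenotype has zero variance")

    @property
    def n(self) -> int:
        return self.values.size


@dataclass
class CovariateTable:
    """Covariates (n x c). Must have full column rank once an intercept is added."""

    values: np.ndarray
    names: Sequence[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim == 1:
            self.values = self.values[:, None]
        if not np.all(np.isfinite(self.values)):
            raise ValueError("covariates contain non-finite values")
        if len(self.names) != self.values.shape[1]:
            raise ValueError("covariate names do not match columns")
        with_intercept = np.column_stack([np.ones(self.values.shape[0]), self.values])
        if np.linalg.matrix_rank(with_intercept) < with_intercept.shape[1]:
            raise ValueError("covariates are collinear with the intercept")

    @property
    def n_covariates(self) -> int:
        return self.values.shape[1]


@dataclass
class PairTestResult:
    """One SNP-pair interaction test (the product-term Wald t-test)."""

    snp1: str
    snp2: str
    b3_hat: float
    se_b3: float
    t_stat: float
    df: int
    p_two_sided: float
    error: Optional[str] = None  # set when the pair was skipped

    @property
    def ok(self) -> bool:
        return self.error is None


@dataclass
class GenePairResult:
    """Gene-level outcome of one combination method on one chunk."""

    gene1: str
    gene2: str
    method: str  # minP | GATES | tTS | tProd | PC
    statistic: float
    p_gene: float
    n_pairs: int
    chunk_id: Optional[str] = None
    n_null_samples: Optional[int] = None
    seed: Optional[int] = None
    extra: dict = field(default_factory=dict)

    def as_row(self) -> dict:
        return {
            "gene1": self.gene1,
            "gene2": self.gene2,
            "chunk": self.chunk_id if self.chunk_id is not None else ".",
            "method": self.method,
            "n_pairs": self.n_pairs,
            "statistic": self.statistic,
            "p_gene": self.p_gene,
            "n_null_samples": self.n_null_samples if self.n_null_samples is not None else ".",
            "seed": self.seed if self.seed is not None else ".",
        }


@dataclass
class TruncationConfig:
    """Truncation threshold and the adaptive null-sampling schedule.

    Stage counts are *additional* draws per stage; with the defaults the
    cumulative ceiling is 10**8 draws, so the smallest attainable empirical
    P value is 1e-8. Each stage is entered only when the running empirical
    P drops below the corresponding threshold.
    """

    tau: float = 0.05
    stages: tuple = (1_000, 99_000, 99_900_000)
    thresholds: tuple = (0.01, 1e-4)

    def __post_init__(self) -> None:
        if not 0 < self.tau < 1:
            raise ValueError("tau must lie in (0, 1)")
        if any(s <= 0 for s in self.stages):
            raise ValueError("stage sample counts must be positive")
        if len(self.thresholds) != len(self.stages) - 1:
            raise ValueError("need one advance threshold per stage transition")

    @property
    def max_draws(self) -> int:
        return int(sum(self.stages))


@dataclass
class GeneModel:
    """A gene (or any locus) as a 1-based inclusive genomic interval."""

    name: str
    chrom: str
    start: int
    end: int
    flank: int = 5_000

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.name}: start > end")

    def contains(self, chrom: str, pos: int) -> bool:
        return (
            str(chrom) == str(self.chrom)
            and self.start - self.flank <= pos <= self.end + self.flank
        )


def results_to_frame(results: Sequence[GenePairResult]) -> pd.DataFrame:
    """Tabulate gene-level results, one row per method per chunk."""
    return pd.DataFrame([r.as_row() for r in results])
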