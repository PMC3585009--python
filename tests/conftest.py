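import numpy as np
import pytest

from gggtest.datatypes import CovariateTable, GenotypeMatrix, PhenotypeVector
from gggtest.simulate import latent_rho_for_allele_corr, _hwe_pair_dosages


@pytest.fixture
def rng():
    return np.random.default_rng(20130228)


def hwe_dosages(f: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """Independent HWE dosages at allele frequency f."""
    return rng.binomial(2, f, size=n).astype(float)


def ld_pair(f1, f2, r, n, rng):
    """Two dosage columns with (approximately) the requested correlation."""
    rho = latent_rho_for_allele_corr(f1, f2, r)
    return _hwe_pair_dosages(f1, f2, rho, n, rng)


@pytest.fixture
def ld_quadruple(rng):
    """Two genes x two SNPs with within-gene LD, for Sigma tests (n=1000)."""
    G1 = ld_pair(0.3, 0.4, 0.55, 1000, rng)
    G2 = ld_pair(0.25, 0.45, 0.4, 1000, rng)
    gm1 = GenotypeMatrix(G1, ["g1a", "g1b"])
    gm2 = GenotypeMatrix(G2, ["g2a", "g2b"])
    return gm1, gm2


def null_t_oracle(s1, s2, Y):
    """Independent textbook OLS oracle: interaction t statistic per column
    of the phenotype matrix Y, via explicit (X'X)^{-1} algebra."""
    n = s1.size
    X = np.column_stack([np.ones(n), s1, s2, s1 * s2])
    XtX_inv = np.linalg.inv(X.T @ X)
    H = XtX_inv @ X.T
    beta = H @ Y
    resid = Y - X @ beta
    sigma2 = np.einsum("nr,nr->r", resid, resid) / (n - 4)
    return beta[3] / np.sqrt(sigma2 * XtX_inv[3, 3])


@pytest.fixture
def small_dataset(rng):
    """Seeded n=80 dataset for exact-oracle comparisons."""
    s1 = hwe_dosages(0.35, 80, rng)
    s2 = hwe_dosages(0.4, 80, rng)
    y = 0.2 * s1 + 0.1 * s2 + 0.25 * s1 * s2 + rng.standard_normal(80)
    covars = CovariateTable(
        values=np.column_stack([rng.standard_normal(80), rng.integers(0, 2, 80)]),
        names=["age", "sex"],
    )
    return PhenotypeVector(values=y), s1, s2, covars
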