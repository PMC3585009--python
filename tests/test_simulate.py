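"""Tests for the synthetic-data generator and simulation harness."""
import numpy as np
import pytest
from scipy import stats

from gggtest.simulate import (
    DEFAULT_LOCUS1,
    DEFAULT_LOCUS2,
    LocusModel,
    ScenarioSpec,
    build_pool,
    calibrate_polynomial,
    default_scenario,
    latent_rho_for_allele_corr,
    run_power,
    run_type1,
    simulate_genotypes,
    simulate_phenotype,
)


@pytest.fixture(scope="module")
def pools():
    return (
        build_pool(DEFAULT_LOCUS1, seed=11),
        build_pool(DEFAULT_LOCUS2, seed=12),
    )


class TestPool:
    def test_maf_calibration(self, pools):
        """Realized pool frequencies within +/-0.01 of targets."""
        for pool in pools:
            assert np.abs(pool.realized_maf() - pool.maf_target).max() < 0.01

    def test_ld_decays_with_distance(self, pools):
        """Dosage correlation falls off with marker index distance."""
        C = pools[0].ld_matrix()
        m = C.shape[0]
        dist, corr = [], []
        for i in range(m):
            for j in range(i + 1, m):
                dist.append(j - i)
                corr.append(C[i, j])
        rho, pval = stats.spearmanr(dist, corr)
        assert rho < 0
        assert pval < 0.01

    def test_loci_in_linkage_equilibrium(self, pools):
        cross = np.array([
            [np.corrcoef(pools[0].dosages[:, i], pools[1].dosages[:, j])[0, 1]
             for j in range(0, 28, 5)]
            for i in range(0, 53, 7)
        ])
        assert np.abs(cross).mean() < 0.02

    def test_extreme_maf_rejected(self):
        locus = LocusModel(n_snps=3, maf=[1e-5, 0.3, 0.4], tags=(1, 2))
        with pytest.raises(ValueError):
            build_pool(locus, n_haplotypes=2000, seed=0)


class TestScenario:
    def test_causal_indices_validated(self):
        with pytest.raises(ValueError):
            default_scenario(causal_pairs=((99, 1),))

    def test_status_derived_from_tags(self):
        spec = default_scenario(causal_pairs=((30, 15), (29, 17)))
        assert spec.causal_status() == [("U", "U"), ("O", "O")]

    def test_genotypes_shape_and_range(self):
        spec = default_scenario(n=300)
        g1, g2 = simulate_genotypes(spec, seed=5)
        assert g1.dosages.shape == (300, 53)
        assert g2.dosages.shape == (300, 28)
        assert g1.dosages.min() >= 0 and g1.dosages.max() <= 2

    def test_null_phenotype_independent_of_genotypes(self):
        spec = default_scenario(n=2000)
        genos = simulate_genotypes(spec, seed=5)
        y = simulate_phenotype(genos, spec, seed=6)
        cors = [
            np.corrcoef(y.values, genos[0].dosages[:, k])[0, 1]
            for k in range(0, 53, 6)
        ]
        assert np.abs(cors).max() < 3 / np.sqrt(2000)

    def test_huge_effect_always_detected(self, rng):
        from gggtest.datatypes import PhenotypeVector
        from gggtest.marker import fit_interaction

        spec = default_scenario(n=500, causal_pairs=((30, 15),), effect_size=5.0,
                                b_main=0.0)
        genos = simulate_genotypes(spec, seed=5)
        y = simulate_phenotype(genos, spec, seed=6)
        res = fit_interaction(
            y, genos[0].dosages[:, 29], genos[1].dosages[:, 14]
        )
        assert res.p_two_sided < 1e-20

    def test_phenotype_variance_matches_moment_algebra(self):
        """Var(y) for a single causal pair equals the HWE moment expansion
        plus the unit error variance (independent oracle)."""
        spec = default_scenario(n=0, causal_pairs=((30, 15),), effect_size=0.3)
        pool1 = build_pool(spec.locus1, seed=21)
        pool2 = build_pool(spec.locus2, seed=22)
        sa = pool1.dosages[:, 29]
        sb = pool2.dosages[:, 14]
        b = 0.3
        rng = np.random.default_rng(3)
        y = b * sa + b * sb + b * sa * sb + rng.standard_normal(sa.size)
        # moment oracle with realized frequencies (HWE: var = 2f(1-f))
        fa, fb = sa.mean() / 2, sb.mean() / 2
        va, vb = 2 * fa * (1 - fa), 2 * fb * (1 - fb)
        mua, mub = 2 * fa, 2 * fb
        ea2, eb2 = va + mua**2, vb + mub**2
        var_prod = ea2 * eb2 - mua**2 * mub**2
        cov_a_prod = mub * va
        cov_b_prod = mua * vb
        expected = (
            b**2 * (va + vb + var_prod)
            + 2 * b * b * (cov_a_prod + cov_b_prod)
            + 1.0
        )
        assert y.var() == pytest.approx(expected, rel=0.05)


class TestHarness:
    def test_same_seed_bitwise_identical(self):
        spec = default_scenario(n=400, replicates=8, seed=42,
                                methods=("minP", "GATES", "tTS", "tProd"))
        a = run_type1(spec)
        b = run_type1(spec)
        assert a.rejections == b.rejections

    def test_zero_effect_power_equals_type1(self):
        spec = default_scenario(
            n=400, replicates=6, seed=9, causal_pairs=((30, 15),),
            effect_size=0.0, methods=("GATES",),
        )
        assert run_power(spec).rejections == run_type1(spec).rejections

    def test_report_mcse(self):
        spec = default_scenario(n=400, replicates=10, seed=1, methods=("GATES",))
        rep = run_type1(spec)
        p = rep.rates["GATES"]
        assert rep.mcse["GATES"] == pytest.approx(np.sqrt(p * (1 - p) / 10))
        assert 0 <= p <= 1

    def test_type1_nominal_with_larger_snp_sets(self):
        """Combining more pairwise tests (30 x 20 SNPs, 600 pairs) keeps the
        type-I error at the nominal level."""
        from gggtest.simulate import _default_maf

        l1 = LocusModel(30, _default_maf(30, {}, seed=91), tags=tuple(range(1, 31)))
        l2 = LocusModel(20, _default_maf(20, {}, seed=92), tags=tuple(range(1, 21)))
        spec = ScenarioSpec(
            locus1=l1, locus2=l2, n=500, replicates=300, seed=14,
            methods=("GATES",),
        )
        rate = run_type1(spec).rates["GATES"]
        assert abs(rate - 0.05) < 3 * np.sqrt(0.05 * 0.95 / 300)

    def test_external_ld_mode_runs(self):
        spec = default_scenario(
            n=400, replicates=5, seed=2, ld_source="external",
            methods=("minP", "tProd"),
        )
        rep = run_type1(spec)
        assert rep.replicates == 5


class TestLatentCalibration:
    def test_roundtrip(self, rng):
        from gggtest.simulate import _hwe_pair_dosages

        rho = latent_rho_for_allele_corr(0.3, 0.4, 0.5)
        G = _hwe_pair_dosages(0.3, 0.4, rho, 200_000, rng)
        assert np.corrcoef(G.T)[0, 1] == pytest.approx(0.5, abs=0.01)

    def test_unattainable_raises(self):
        with pytest.raises(ValueError, match="unattainable"):
            latent_rho_for_allele_corr(0.05, 0.5, -0.9)


class TestCalibratePolynomial:
    def test_perfect_correlation_point(self, rng):
        """r1 = r2 = 1 with equal frequencies maps to (x, y) near (1, 1)."""
        from gggtest.simulate import QuadrupleConfig

        res = calibrate_polynomial(
            configs=[QuadrupleConfig(0.99, 0.99, (0.3, 0.3, 0.4, 0.4))],
            n=800, reps=600, seed=4,
        )
        assert res["x"][0] == pytest.approx(1.0, abs=0.03)
        assert res["y"][0] == pytest.approx(1.0, abs=0.03)
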