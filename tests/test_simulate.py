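"""Simulator: HWE genotypes, bivariate phenotypes, per-SNP GWAS, study runner."""

import math

import numpy as np
import pandas as pd
import pytest

from phenocorr.estimators import OverlapSpec
from phenocorr.simulate import (
    DEFAULT_METHOD_GRID,
    MafSpectrum,
    SimConfig,
    monomorphic_mask,
    random_snp_estimator,
    run_gwas,
    run_simulation_study,
    sample_mafs,
    simulate_binary_pair,
    simulate_genotypes,
    simulate_phenotype_pair,
    simulate_replicate,
    simulate_single_snp_zscores,
)
from phenocorr.theory import SnpModelParams, zscore_cor_theory


class TestSampleMafs:
    def test_default_spectrum_range_and_tail(self):
        f = sample_mafs(10000, seed=3)
        assert f.min() >= 1e-4 and f.max() <= 0.5
        # log-uniform tail mass below 5e-4 is ln(5)/ln(5000) ~ 0.189
        expected = 10000 * MafSpectrum().tail_mass(5e-4)
        assert expected > 100
        assert abs((f < 5e-4).sum() - expected) < 5 * math.sqrt(expected)

    def test_point_mass(self):
        f = sample_mafs(50, MafSpectrum(family="point", value=0.3), seed=0)
        assert (f == 0.3).all()

    def test_seed_determinism(self):
        np.testing.assert_array_equal(sample_mafs(100, seed=7), sample_mafs(100, seed=7))

    def test_invalid_spectrum(self):
        with pytest.raises(ValueError):
            MafSpectrum(f_min=0.0)
        with pytest.raises(ValueError):
            MafSpectrum(family="weird")


class TestSimulateGenotypes:
    def test_hwe_moments(self):
        g = simulate_genotypes(10000, np.full(50, 0.5), seed=1)
        assert set(np.unique(g)) <= {0, 1, 2}
        # HWE: mean 2f = 1, variance 2f(1-f) = 0.5; 5-SE bands
        se_mean = math.sqrt(0.5 / 10000)
        assert abs(g.mean() - 1.0) < 5 * se_mean / math.sqrt(50)
        assert abs(g.var() - 0.5) < 0.02

    def test_rare_snp_monomorphic_flagged(self):
        g = simulate_genotypes(100, np.full(200, 1e-4), seed=2)
        mask = monomorphic_mask(g)
        assert mask.mean() > 0.9  # expected heterozygote count 0.02

    def test_determinism(self):
        f = sample_mafs(30, seed=0)
        np.testing.assert_array_equal(
            simulate_genotypes(50, f, seed=9), simulate_genotypes(50, f, seed=9)
        )


class TestPhenotypePair:
    def test_pure_residual_pair_recovers_re(self):
        cfg = SimConfig(n1=20000, n2=20000, n0=20000, m=50, h2_1=0.0, h2_2=0.0,
                        r_g=0.0, r_e=0.35,
                        maf_spectrum=MafSpectrum(family="point", value=0.3))
        pair = simulate_phenotype_pair(cfg, seed=4)
        assert pair.true_r_p_individual == pytest.approx(0.35, abs=5 / math.sqrt(20000))

    @pytest.mark.parametrize("scale", ["standardized", "allele_count"])
    def test_full_overlap_truth_recovery(self, scale):
        """Empirical phenotype correlation matches the closed-form truth."""
        cfg = SimConfig(n1=20000, n2=20000, n0=20000, m=400, causal_prop=1.0,
                        h2_1=0.5, h2_2=0.5, r_g=0.5, r_e=0.5, effect_scale=scale,
                        maf_spectrum=MafSpectrum(family="uniform", f_min=0.05, f_max=0.5))
        assert cfg.true_r_p == pytest.approx(0.5)
        vals = [simulate_phenotype_pair(cfg, seed=s).true_r_p_individual
                for s in range(5)]
        # per-replicate truth fluctuates with the realized effect draws
        assert np.mean(vals) == pytest.approx(0.5, abs=0.03)

    def test_asymmetric_heritability_truth(self):
        cfg = SimConfig(n1=30000, n2=30000, n0=30000, m=400, causal_prop=1.0,
                        h2_1=0.3, h2_2=0.3, r_g=0.5, r_e=0.25,
                        maf_spectrum=MafSpectrum(family="uniform", f_min=0.05, f_max=0.5))
        assert cfg.true_r_p == pytest.approx(0.325)
        vals = [simulate_phenotype_pair(cfg, seed=s).true_r_p_individual
                for s in range(4)]
        assert np.mean(vals) == pytest.approx(0.325, abs=0.03)

    def test_zero_overlap_truth_undefined(self):
        cfg = SimConfig(n1=500, n2=500, n0=0, m=100)
        pair = simulate_phenotype_pair(cfg, seed=0)
        assert pair.true_r_p_individual is None
        assert len(pair.y1) == 500 and len(pair.y2) == 500
        assert not np.intersect1d(pair.idx1, pair.idx2).size

    def test_phenotypes_centered_and_deterministic(self):
        cfg = SimConfig(n1=400, n2=400, n0=200, m=300, seed=11)
        p1 = simulate_phenotype_pair(cfg)
        p2 = simulate_phenotype_pair(cfg)
        np.testing.assert_array_equal(p1.y1, p2.y1)
        assert p1.y1.mean() == pytest.approx(0.0, abs=1e-12)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SimConfig(n0=3000)  # n0 > min(n1, n2)
        with pytest.raises(ValueError):
            SimConfig(h2_1=1.5)
        with pytest.raises(ValueError):
            SimConfig(m=100, causal_prop=0.001)  # causal count 0 with h2 > 0


class TestRunGwas:
    def test_null_z_standard_normal(self, rng):
        n, m = 3000, 1500
        g = simulate_genotypes(n, np.full(m, 0.3), rng)
        y = rng.standard_normal(n)
        res = run_gwas(g, y)
        assert abs(res.z.mean()) < 5 / math.sqrt(m)
        assert abs(res.z.var() - 1.0) < 5 * math.sqrt(2 / m)

    def test_perfect_snp(self, rng):
        n = 500
        g = simulate_genotypes(n, np.full(20, 0.3), rng)
        y = g[:, 7].astype(float)
        res = run_gwas(g, y - y.mean())
        i = np.where(res.snp_index == 7)[0][0]
        assert res.beta_hat[i] == pytest.approx(1.0)
        assert np.argmax(np.abs(res.z)) == i

    def test_monomorphic_dropped_and_z_consistent(self, rng):
        g = simulate_genotypes(200, np.array([0.3, 1e-6, 0.4]), rng)
        g[:, 1] = 0
        res = run_gwas(g, rng.standard_normal(200))
        assert 1 not in res.snp_index
        np.testing.assert_allclose(res.z, res.beta_hat / res.se)
        assert (res.se > 0).all()

    def test_single_snp_matches_theory(self):
        """Empirical cor(z1, z2) across replicates agrees with the closed form."""
        p = SnpModelParams(f=0.1, sigma_b1_sq=0.01, sigma_b2_sq=0.01,
                           r_g=0.5, r_e=0.4)
        ov = OverlapSpec(600, 600, 300)
        z1, z2 = simulate_single_snp_zscores(p, ov, n_reps=3000, seed=21)
        emp = np.corrcoef(z1, z2)[0, 1]
        th = zscore_cor_theory(p, ov)
        mc_se = (1 - th * th) / math.sqrt(len(z1))
        assert emp == pytest.approx(th, abs=3 * mc_se)


class TestRandomSnpEstimator:
    def test_full_overlap_matches_individual_truth(self):
        cfg = SimConfig(n1=3000, n2=3000, n0=3000, m=50, h2_1=0.0, h2_2=0.0,
                        r_g=0.0, r_e=0.5,
                        maf_spectrum=MafSpectrum(family="point", value=0.3))
        ests, truths = [], []
        for s in range(5):
            pair = simulate_phenotype_pair(cfg, seed=s)
            est = random_snp_estimator(pair, seed=s + 100)
            assert est.method == "random_snp" and est.n_snps == 500
            ests.append(est.r_raw)
            truths.append(pair.true_r_p_individual)
        # SE of one 500-SNP estimate ~ (1-r^2)/sqrt(500) ~ 0.034
        assert np.mean(ests) == pytest.approx(np.mean(truths), abs=3 * 0.034 / math.sqrt(5))

    def test_zero_overlap_mean_zero(self):
        cfg = SimConfig(n1=1500, n2=1500, n0=0, m=50, h2_1=0.0, h2_2=0.0,
                        r_g=0.0, r_e=0.5,
                        maf_spectrum=MafSpectrum(family="point", value=0.3))
        ests = [random_snp_estimator(simulate_phenotype_pair(cfg, seed=s),
                                     seed=s).r_raw for s in range(5)]
        assert np.mean(ests) == pytest.approx(0.0, abs=3 * 0.045 / math.sqrt(5))

    def test_deterministic(self):
        cfg = SimConfig(n1=500, n2=500, n0=500, m=50,
                        maf_spectrum=MafSpectrum(family="point", value=0.3))
        pair = simulate_phenotype_pair(cfg, seed=3)
        a = random_snp_estimator(pair, seed=9)
        b = random_snp_estimator(pair, seed=9)
        assert a.r_raw == b.r_raw


class TestBinaryPair:
    def test_prevalence_and_liability_truth(self):
        cfg = SimConfig(n1=8000, n2=8000, n0=8000, m=200, h2_1=0.0, h2_2=0.0,
                        r_g=0.0, r_e=0.5, prevalence_1=0.5, prevalence_2=0.2,
                        maf_spectrum=MafSpectrum(family="point", value=0.3))
        b1, b2, pair = simulate_binary_pair(cfg, seed=6)
        assert b1.mean() == pytest.approx(0.5, abs=0.01)
        assert b2.mean() == pytest.approx(0.2, abs=0.01)
        assert pair.true_r_p_individual == pytest.approx(0.5, abs=0.05)
        # observed 0/1 correlation is attenuated relative to the liability scale
        assert np.corrcoef(b1, b2)[0, 1] < pair.true_r_p_individual

    def test_degenerate_prevalence_errors(self):
        cfg = SimConfig(n1=100, n2=100, n0=100, m=20, prevalence_1=1.0,
                        prevalence_2=0.5)
        with pytest.raises(ValueError):
            simulate_binary_pair(cfg, seed=0)
        with pytest.raises(ValueError):
            simulate_binary_pair(SimConfig(n1=100, n2=100, n0=100, m=20), seed=0)

    def test_unbalanced_case_control_sign_preserved(self):
        """Rare-disease GWAS on 0/1 outcomes keeps a positive Z correlation."""
        cfg = SimConfig(n1=4000, n2=4000, n0=4000, m=4000, h2_1=0.0, h2_2=0.0,
                        r_g=0.0, r_e=0.5, prevalence_1=0.05, prevalence_2=0.05)
        b1, b2, pair = simulate_binary_pair(cfg, seed=8)
        g = simulate_genotypes(cfg.n_total, sample_mafs(cfg.m, seed=8), seed=88)
        gw1 = run_gwas(g, b1 - b1.mean())
        gw2 = run_gwas(g, b2 - b2.mean())
        shared = np.intersect1d(gw1.snp_index, gw2.snp_index)
        i1 = np.searchsorted(gw1.snp_index, shared)
        i2 = np.searchsorted(gw2.snp_index, shared)
        r = np.corrcoef(gw1.z[i1], gw2.z[i2])[0, 1]
        assert r > 0.2  # sign and rough magnitude of the liability correlation


class TestStudyRunner:
    def test_grid_plumbing_and_failure_marking(self):
        cfg = SimConfig(n1=300, n2=300, n0=300, m=2000, seed=0)
        methods = (("low_maf", 0.5), ("low_maf", 1e-6), ("z_cut", 1.0),
                   ("random_snp", None))
        res = run_simulation_study({"s0": cfg}, replicates=2, seed=5,
                                   methods=methods)
        rec = res.records
        # every replicate x method cell present, plus the individual-level truth
        assert len(rec) == 2 * (len(methods) + 1)
        # the unreachable MAF cutoff fails gracefully, run continues
        failed = rec[rec["failed"]]
        assert set(failed["cutoff"]) == {1e-6}
        summary = res.summary()
        assert {"mean_estimate", "sd_estimate", "mean_se", "se_sd_ratio"} <= set(summary.columns)

    def test_determinism(self):
        cfg = SimConfig(n1=200, n2=200, n0=100, m=1000)
        a = run_simulation_study(cfg, replicates=2, seed=42,
                                 methods=(("low_maf", 0.5),))
        b = run_simulation_study(cfg, replicates=2, seed=42,
                                 methods=(("low_maf", 0.5),))
        pd.testing.assert_frame_equal(a.records, b.records)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            run_simulation_study({}, replicates=1, seed=0)
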