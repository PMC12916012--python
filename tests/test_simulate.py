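import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hdlc import (
    SimScenario,
    draw_effects,
    gwas_zscores,
    run_scenario,
    sample_top_snp_h2,
    simulate_genotypes,
    simulate_ld_ar1,
    simulate_phenotypes,
    simulate_sumstats_direct,
    simulate_sumstats_from_effects,
)
from hdlc.simulate import read_scenario, write_scenario


class TestDrawEffects:
    def test_perfect_correlation_degenerate(self):
        rng = np.random.default_rng(0)
        b1, b2 = draw_effects(100, 0.02, 0.02, 1.0, rng)
        assert np.allclose(b1, b2)

    def test_independent_effects_uncorrelated(self):
        rng = np.random.default_rng(1)
        b1, b2 = draw_effects(40_000, 0.1, 0.1, 0.0, rng)
        assert abs(np.corrcoef(b1, b2)[0, 1]) < 0.03

    def test_monte_carlo_covariance(self):
        m, h1, h2, rg = 50_000, 0.05, 0.2, 0.6
        rng = np.random.default_rng(2)
        b1, b2 = draw_effects(m, h1, h2, rg, rng)
        emp = np.cov(b1, b2)
        target = np.array(
            [[h1 / m, rg * np.sqrt(h1 * h2) / m], [rg * np.sqrt(h1 * h2) / m, h2 / m]]
        )
        assert np.all(np.abs(emp - target) <= 0.05 * np.abs(target) + 1e-12)

    def test_invalid_correlation(self):
        with pytest.raises(ValueError):
            draw_effects(10, 0.1, 0.1, 1.5, np.random.default_rng(0))


class TestGenotypes:
    def test_identity_ld_gives_uncorrelated_columns(self):
        block = simulate_ld_ar1(20, 0.0)
        X = simulate_genotypes(3000, block, np.random.default_rng(3))
        off = np.corrcoef(X.T) - np.eye(20)
        assert np.max(np.abs(off)) < 0.08

    def test_empirical_correlation_converges_to_R(self, ar1_block):
        X = simulate_genotypes(5000, ar1_block, np.random.default_rng(4))
        assert np.max(np.abs(np.corrcoef(X.T) - ar1_block.R)) <= 0.05

    def test_same_seed_bit_identical(self, ar1_block):
        X1 = simulate_genotypes(100, ar1_block, np.random.default_rng(5))
        X2 = simulate_genotypes(100, ar1_block, np.random.default_rng(5))
        assert np.array_equal(X1, X2)

    def test_discretized_mode_standardized(self, ar1_block):
        X = simulate_genotypes(
            2000, ar1_block, np.random.default_rng(6), discretize=True, maf=0.3
        )
        assert np.allclose(X.mean(axis=0), 0.0, atol=1e-12)
        assert np.allclose(X.std(axis=0), 1.0, atol=1e-12)


class TestPhenotypes:
    def test_pure_noise_unit_variance(self):
        X = np.zeros((5000, 3))
        y = simulate_phenotypes(
            X, np.array([0]), np.array([0.0]), 0.0, np.random.default_rng(7)
        )
        assert np.var(y) == pytest.approx(1.0, abs=0.1)

    def test_total_variance_near_one(self, ar1_block):
        # across replicates at h2 = 0.1 the phenotypic variance centers on 1
        variances = []
        for i in range(200):
            rng = np.random.default_rng(10_000 + i)
            X = simulate_genotypes(500, ar1_block, rng)
            idx = rng.choice(ar1_block.M, 5, replace=False)
            b1, _ = draw_effects(5, 0.1, 0.1, 0.0, rng)
            y = simulate_phenotypes(X, idx, b1, 0.1, rng)
            variances.append(np.var(y))
        assert np.mean(variances) == pytest.approx(1.0, abs=0.05)

    def test_genetic_component_linear_in_beta(self, ar1_block):
        rng_geno = np.random.default_rng(8)
        X = simulate_genotypes(200, ar1_block, rng_geno)
        idx = np.array([0, 1])
        beta = np.array([0.3, -0.2])
        y1 = simulate_phenotypes(X, idx, beta, 0.0, np.random.default_rng(9))
        y2 = simulate_phenotypes(X, idx, 2 * beta, 0.0, np.random.default_rng(9))
        # identical residual stream: difference is exactly the genetic part
        assert np.allclose(y2 - y1, X[:, idx] @ beta)

    def test_h_sq_bounds(self):
        with pytest.raises(ValueError):
            simulate_phenotypes(
                np.zeros((10, 2)), np.array([0]), np.array([1.0]), 1.0,
                np.random.default_rng(0),
            )


class TestGwasZscores:
    def test_null_mean_z2_near_one(self):
        rng = np.random.default_rng(11)
        block = simulate_ld_ar1(100, 0.5)
        X = simulate_genotypes(10_000, block, rng)
        y = rng.standard_normal(10_000)
        z = gwas_zscores(X, y)
        assert np.mean(z**2) == pytest.approx(1.0, abs=0.15)

    def test_degenerate_column_finite_huge(self):
        rng = np.random.default_rng(12)
        x = rng.standard_normal(500)
        X = np.column_stack([x, rng.standard_normal(500)])
        X = (X - X.mean(0)) / X.std(0)
        z = gwas_zscores(X, X[:, 0])
        assert np.isfinite(z[0]) and abs(z[0]) > 1e5

    def test_second_moment_matches_model(self):
        # E[z_j^2] = 1 + (N h2 / M) * ld_score_j under the all-causal model
        block = simulate_ld_ar1(50, 0.8)
        N, h = 20_000, 0.01
        acc = np.zeros(block.M)
        reps = 60
        for i in range(reps):
            rng = np.random.default_rng(20_000 + i)
            X = simulate_genotypes(N, block, rng)
            b1, _ = draw_effects(block.M, h, h, 0.0, rng)
            y = simulate_phenotypes(X, np.arange(block.M), b1, h, rng)
            acc += gwas_zscores(X, y) ** 2
        expected = 1.0 + N * h / block.M * block.ld_scores
        ratio = np.mean(acc / reps) / np.mean(expected)
        assert abs(ratio - 1.0) <= 0.10


class TestDirectSampler:
    def test_same_seed_identical(self, ar1_block):
        a = simulate_sumstats_direct(
            ar1_block, 0.05, 0.05, 0.02, 1e4, 1e4, np.random.default_rng(1)
        )
        b = simulate_sumstats_direct(
            ar1_block, 0.05, 0.05, 0.02, 1e4, 1e4, np.random.default_rng(1)
        )
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_null_covariance_matches_R(self):
        block = simulate_ld_ar1(15, 0.6)
        draws = []
        for i in range(4000):
            rng = np.random.default_rng(30_000 + i)
            z1, _ = simulate_sumstats_direct(block, 0, 0, 0, 1e4, 1e4, rng)
            draws.append(z1)
        emp = np.cov(np.array(draws).T)
        assert np.max(np.abs(emp - block.R)) <= 0.1

    def test_invalid_h12_rejected(self, ar1_block):
        with pytest.raises(ValueError):
            simulate_sumstats_direct(
                ar1_block, 0.01, 0.01, 0.05, 1e4, 1e4, np.random.default_rng(0)
            )

    def test_cross_simulator_concordance(self):
        # Lambda distribution agrees between the individual-level pipeline
        # and the model sampler at an all-causal grid point (KS test)
        block = simulate_ld_ar1(40, 0.7)
        h, rg, N = 0.02, 0.5, 8_000
        base = dict(
            M=40, ld_rho=0.7, architecture=1.0, h1_sq_grid=(h,),
            h2_sq_grid=(h,), rg_grid=(rg,), N1=N, N2=N, n_replicates=120,
        )
        direct = run_scenario(
            SimScenario(mode="direct", seed=1, **base), r0_list=(0.0,)
        )
        indiv = run_scenario(
            SimScenario(mode="individual", seed=2, **base), r0_list=(0.0,)
        )
        ks = stats.ks_2samp(direct["lambda"], indiv["lambda"])
        assert ks.pvalue > 0.01


class TestScenario:
    def test_grid_row_count(self):
        scn = SimScenario(
            M=30, ld_rho=0.5, architecture=0.1, h1_sq_grid=(0.05,),
            h2_sq_grid=(0.01, 0.1), rg_grid=(0.0, 0.5), N1=1e4, N2=1e4,
            n_replicates=5, seed=3,
        )
        df = run_scenario(scn, r0_list=(0.0, 0.5))
        assert len(df) == 2 * 2 * 5 * 2  # h2 x rg x reps x r0

    def test_rerun_identical(self, tmp_path):
        scn = SimScenario(
            M=25, architecture=0.2, h1_sq_grid=(0.05,), h2_sq_grid=(0.05,),
            rg_grid=(0.5,), N1=1e4, N2=1e4, n_replicates=4, seed=7,
        )
        df1 = run_scenario(scn, r0_list=(0.0,))
        df2 = run_scenario(scn, r0_list=(0.0,))
        pd.testing.assert_frame_equal(df1, df2)

    def test_resume_skips_done_cells(self):
        scn = SimScenario(
            M=25, architecture=0.2, h1_sq_grid=(0.05,), h2_sq_grid=(0.05,),
            rg_grid=(0.0, 0.5), N1=1e4, N2=1e4, n_replicates=4, seed=7,
        )
        full = run_scenario(scn, r0_list=(0.0,))
        half = full.iloc[: len(full) // 2]
        resumed = run_scenario(scn, r0_list=(0.0,), existing=half)
        assert len(resumed) == len(full)
        merged = resumed.sort_values(["cell", "replicate"]).reset_index(drop=True)
        ref = full.sort_values(["cell", "replicate"]).reset_index(drop=True)
        pd.testing.assert_frame_equal(merged, ref)

    def test_single_causal_grid_accepted(self):
        scn = SimScenario(
            M=30, architecture=1, h1_sq_grid="top-snp", h2_sq_grid=(1e-4,),
            rg_grid=(0.0, -1.0, 1.0), N1=1e4, N2=1e4, n_replicates=2, seed=5,
        )
        df = run_scenario(scn, r0_list=(0.0,))
        assert len(df) == 6
        assert np.all((df["true_h1_sq"] > 0) & (df["true_h1_sq"] < 1))

    def test_scenario_roundtrip(self, tmp_path):
        scn = SimScenario(
            M=30, architecture=3, h1_sq_grid="top-snp", h2_sq_grid=(1e-3, 1e-2),
            rg_grid=(0.0, 1.0), N1=2e4, N2=3e4, n_replicates=7, mode="direct",
            seed=11,
        )
        path = tmp_path / "scenario.txt"
        write_scenario(scn, path)
        assert read_scenario(path) == scn

    def test_invalid_scenarios_rejected(self):
        with pytest.raises(ValueError):
            SimScenario(architecture=0.0)
        with pytest.raises(ValueError):
            SimScenario(rg_grid=(1.5,))
        with pytest.raises(ValueError):
            SimScenario(mode="other")

    def test_top_snp_standin_range(self):
        draws = sample_top_snp_h2(np.random.default_rng(1), 5000)
        assert np.all((draws >= 1e-4) & (draws <= 0.5))
        assert 0.01 < np.median(draws) < 0.08


class TestEffectConditionalSampler:
    def test_reduces_to_model_moments_when_all_causal(self):
        block = simulate_ld_ar1(15, 0.5)
        N, h = 5e4, 0.05
        draws = []
        for i in range(3000):
            rng = np.random.default_rng(50_000 + i)
            b1, b2 = draw_effects(block.M, h, h, 0.0, rng)
            z1, _ = simulate_sumstats_from_effects(
                block, b1, b2, np.arange(block.M), N, N, rng
            )
            draws.append(z1)
        emp = np.cov(np.array(draws).T)
        model = N * h / block.M * block.L + block.R
        assert np.max(np.abs(emp - model) / np.abs(model).max()) <= 0.1

    def test_distinct_causal_sets_supported(self):
        block = simulate_ld_ar1(20, 0.5)
        rng = np.random.default_rng(0)
        z1, z2 = simulate_sumstats_from_effects(
            block, np.array([0.5]), np.array([0.5]), np.array([2]),
            1e4, 1e4, rng, causal_idx2=np.array([15]),
        )
        assert abs(z1[2]) > abs(z1[15])
        assert abs(z2[15]) > abs(z2[2])
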