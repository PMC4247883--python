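import numpy as np
import pandas as pd
import pytest

from gpscore.data_model import ConfigurationError, Panel, SnpDef
from gpscore.gps_score import compute_scores
from gpscore.io import write_genotypes_tsv
from gpscore.snp_qc import genotype_counts, hwe_chi2
from gpscore.synthetic_cohort import (
    FEMALE_FRACTION,
    SimulationConfig,
    apply_missingness,
    default_config,
    panel_score_mean,
    panel_score_variance,
    simulate_bmi,
    simulate_cohort,
    simulate_covariates,
    simulate_genotypes,
    simulate_obesity,
)


def tiny_panel(eafs=(0.0, 0.39, 0.8)):
    return Panel((
        SnpDef("rs1", "A1", "A", "G", 0.2, reference_eaf=eafs[0]),
        SnpDef("rs2", "A2", "C", "T", 0.3, reference_eaf=eafs[1]),
        SnpDef("rs3", "A3", "T", "G", 0.1, reference_eaf=eafs[2]),
    ))


class TestGenotypes:
    def test_zero_eaf_gives_all_reference_genotypes(self):
        m = simulate_genotypes(tiny_panel(), 200, seed=1)
        assert (m.df["rs1"] == 0).all()

    def test_sample_eaf_close_to_truth(self):
        n = 5000
        m = simulate_genotypes(tiny_panel(), n, seed=2)
        counts = genotype_counts(m, "rs2")
        eaf = (counts[1] + 2 * counts[2]) / (2 * n)
        se = np.sqrt(0.39 * 0.61 / (2 * n))
        assert abs(eaf - 0.39) < 3 * se

    def test_missing_eaf_rejected(self):
        panel = Panel((SnpDef("rs1", "A", "A", "G", 0.2),))
        with pytest.raises(ValueError):
            simulate_genotypes(panel, 10, seed=0)

    def test_generated_columns_pass_hwe_at_nominal_rate(self):
        """Generated genotypes are in HWE: the chi-square test rejects ~5%."""
        rng = np.random.default_rng(10)
        n, reps = 500, 1000
        genos = rng.binomial(2, 0.39, size=(reps, n))
        rejections = sum(
            hwe_chi2(((g == 0).sum(), (g == 1).sum(), (g == 2).sum())).p <= 0.05
            for g in genos
        )
        assert 0.03 <= rejections / reps <= 0.07


class TestMissingness:
    def test_rate_zero_is_identity(self):
        m = simulate_genotypes(tiny_panel(), 100, seed=3)
        out = apply_missingness(m, 0.0, seed=4)
        pd.testing.assert_frame_equal(out.df, m.df)

    def test_observed_fraction_matches_rate(self):
        m = simulate_genotypes(tiny_panel((0.5, 0.5, 0.5)), 4000, seed=5)
        out = apply_missingness(m, 0.05, seed=6)
        frac = out.df.isna().to_numpy().mean()
        assert abs(frac - 0.05) < 0.005

    def test_same_seed_reproduces(self):
        m = simulate_genotypes(tiny_panel((0.5, 0.5, 0.5)), 300, seed=7)
        a = apply_missingness(m, 0.1, seed=8)
        b = apply_missingness(m, 0.1, seed=8)
        pd.testing.assert_frame_equal(a.df, b.df)


class TestCovariates:
    def test_ranges_and_levels(self):
        cov = simulate_covariates(3000, seed=9)
        assert cov["age"].between(30, 64).all()
        assert set(cov["activity"].unique()) == {"none", "low", "medium", "high"}
        assert abs((cov["sex"] == "female").mean() - FEMALE_FRACTION) < 0.03


class TestBmiModel:
    def test_zero_noise_zero_covariates_is_affine_in_score(self):
        panel = tiny_panel((0.2, 0.39, 0.8))
        # shrink total SD to the genetic SD so the noise budget is ~zero
        genetic_sd = 0.15 * np.sqrt(panel_score_variance(panel))
        cfg = SimulationConfig(panel=panel, n=300, covariate_r2=0.0,
                               bmi_per_allele=0.15,
                               bmi_total_sd=genetic_sd * 1.0001, seed=0)
        m = simulate_genotypes(panel, 300, seed=1)
        weights = np.array([s.weight for s in panel.snps])
        from gpscore.gps_score import rescale_score
        gps = pd.Series(rescale_score(m.df.to_numpy() @ weights, panel),
                        index=m.df.index)
        cov = simulate_covariates(300, seed=2)
        cov.index = m.df.index
        out = simulate_bmi(gps, cov, cfg, seed=3)
        fitted = np.polyfit(gps, out["bmi"], 1)
        assert fitted[0] == pytest.approx(0.15, abs=0.002)

    def test_infeasible_variance_budget_raises(self):
        panel = tiny_panel((0.2, 0.39, 0.8))
        cfg = SimulationConfig(panel=panel, n=100, bmi_total_sd=0.01, seed=0)
        m = simulate_genotypes(panel, 100, seed=1)
        gps = pd.Series(np.zeros(100), index=m.df.index)
        cov = simulate_covariates(100, seed=2)
        cov.index = m.df.index
        with pytest.raises(ConfigurationError, match="variance budget"):
            simulate_bmi(gps, cov, cfg, seed=3)

    def test_quetelet_consistency_of_derived_weight_height(self):
        cohort = simulate_cohort(default_config(seed=4, n=400))
        bmi_back = cohort.phenotypes["weight"] / cohort.phenotypes["height"] ** 2
        np.testing.assert_allclose(bmi_back, cohort.truth["bmi_true"], rtol=1e-10)

    def test_variance_bookkeeping(self):
        """Empirical crude/covariate R² match the configured budget (3 MC SEs)."""
        from gpscore.association import fit_linear, DEFAULT_ADJUSTMENT
        from gpscore.data_model import derive_anthropometrics

        crude, full, total_sd = [], [], []
        for seed in range(30):
            cohort = simulate_cohort(default_config(seed=seed, missing_rate=0.0))
            phen = derive_anthropometrics(cohort.phenotypes.drop(columns=["obese"]))
            gps = cohort.truth["gps_true"]
            res = fit_linear(phen["bmi"], gps, phen, DEFAULT_ADJUSTMENT)
            crude.append(res.r2_crude_percent)
            full.append(res.r2_percent)
            total_sd.append(phen["bmi"].std(ddof=1))
        cfg = default_config()
        expected_crude = 100 * (0.15**2 * panel_score_variance(cfg.panel)) / cfg.bmi_total_sd**2
        for observed, expected in ((crude, expected_crude),
                                   (full, expected_crude + 100 * cfg.covariate_r2)):
            mc_se = np.std(observed, ddof=1) / np.sqrt(len(observed))
            # small upward allowance: sample R² is biased up by ~k/n
            assert abs(np.mean(observed) - expected) < 3 * mc_se + 1.0
        assert np.mean(total_sd) == pytest.approx(cfg.bmi_total_sd, abs=0.25)


class TestObesity:
    def test_threshold_labels_agree_with_bmi_classification(self):
        from gpscore.data_model import classify_bmi

        cohort = simulate_cohort(default_config(seed=11, n=500))
        expected = (classify_bmi(cohort.truth["bmi_true"]) == "obese").astype(int)
        np.testing.assert_array_equal(cohort.phenotypes["obese"].to_numpy(), expected)

    def test_logistic_null_hits_target_prevalence_with_or_one(self):
        from gpscore.association import fit_logistic

        cfg = default_config(seed=12, n=4000, disease_mode="logistic",
                             or_per_allele=1.0, covariate_logodds_per_sd=0.0)
        cohort = simulate_cohort(cfg)
        prev = cohort.phenotypes["obese"].mean()
        assert prev == pytest.approx(cfg.target_prevalence, abs=0.025)
        res = fit_logistic(cohort.phenotypes["obese"],
                           cohort.truth["gps_true"])
        assert res.or_value == pytest.approx(1.0, abs=0.03)

    def test_unreachable_prevalence_raises(self):
        # a score so polarised that prevalence is pinned at 1/2 for any intercept
        panel = tiny_panel((0.2, 0.39, 0.8))
        gps = pd.Series(np.r_[np.full(25, -1e6), np.full(25, 1e6)],
                        index=[f"S{i:05d}" for i in range(50)])
        cov = simulate_covariates(50, seed=1)
        cov.index = gps.index
        cfg = SimulationConfig(panel=panel, disease_mode="logistic",
                               target_prevalence=0.05, covariate_logodds_per_sd=0.0,
                               seed=0)
        with pytest.raises(ConfigurationError):
            simulate_obesity(gps, cov, cfg, seed=2)

    def test_invalid_config_rejected(self):
        panel = tiny_panel()
        with pytest.raises(ConfigurationError):
            SimulationConfig(panel=panel, missing_rate=1.5)
        with pytest.raises(ConfigurationError):
            SimulationConfig(panel=panel, disease_mode="magic")
        with pytest.raises(ConfigurationError):
            SimulationConfig(panel=panel, or_per_allele=-2)


class TestDeterminism:
    def test_identical_config_gives_byte_identical_files(self, tmp_path):
        a = simulate_cohort(default_config(seed=99, n=120))
        b = simulate_cohort(default_config(seed=99, n=120))
        pa, pb = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_genotypes_tsv(a.genotypes, pa)
        write_genotypes_tsv(b.genotypes, pb)
        assert pa.read_bytes() == pb.read_bytes()
        pd.testing.assert_frame_equal(a.phenotypes, b.phenotypes)

    def test_different_seeds_differ(self):
        a = simulate_cohort(default_config(seed=1, n=100))
        b = simulate_cohort(default_config(seed=2, n=100))
        assert not a.genotypes.df.equals(b.genotypes.df)
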