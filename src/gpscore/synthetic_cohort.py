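"""Synthetic genotype-phenotype cohorts with the structure the analysis assumes.

The generator emulates a cross-sectional adult cohort (ages 30-64, slight
female majority) genotyped on a weighted BMI SNP panel:

* genotypes are independent across SNPs and drawn in Hardy-Weinberg
  proportions, binomial(2, EAF) at each SNP's truth frequency;
* genotype calls go missing completely at random at a configurable rate
  (default 5%, the panel's guaranteed minimum call rate);
* BMI is an additive function of the allele-unit score (default 0.15 kg/m²
  per risk allele), a covariate term calibrated in closed form to a target
  share of variance (default 13.1%), and Gaussian noise filling the rest of
  a total-SD budget (default 5.5 kg/m²);
* obesity is produced either by thresholding BMI at 30 (threshold mode) or
  from a per-allele odds ratio acting on the score directly (logistic mode,
  default OR 1.11, prevalence solved to a target among cases+controls).

Everything is driven by a single integer seed; the same configuration and
seed reproduce the cohort exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, special

from .data_model import ConfigurationError, GenotypeMatrix, Panel, classify_bmi
from .gps_score import rescale_score

#: Fraction of women, matching the 409/787 split of the emulated cohort.
FEMALE_FRACTION = 409 / 787
AGE_RANGE = (30.0, 64.0)
SMOKING_PROBS = {"never": 0.55, "current": 0.25, "former": 0.20}


@dataclass(frozen=True)
class SimulationConfig:
    """Ground-truth parameters of a simulated cohort.

    The defaults describe the emulated study: n = 740 analysed adults, 5%
    missing calls, +0.15 kg/m² BMI per risk allele, covariates worth 13.1%
    of a 5.5 kg/m² total BMI standard deviation, and (in logistic mode) a
    per-allele obesity odds ratio of 1.11 at 33% prevalence.
    """

    panel: Panel
    n: int = 740
    missing_rate: float = 0.05
    max_missing: int = 3
    bmi_per_allele: float = 0.15
    bmi_total_sd: float = 5.5
    bmi_mean: float = 26.5
    covariate_r2: float = 0.131
    disease_mode: str = "threshold"  # or "logistic"
    or_per_allele: float = 1.11
    target_prevalence: float = 0.33
    covariate_logodds_per_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.missing_rate < 1.0:
            raise ConfigurationError("missing_rate must lie in [0, 1)")
        if self.or_per_allele <= 0:
            raise ConfigurationError("or_per_allele must be positive")
        if self.disease_mode not in ("threshold", "logistic"):
            raise ConfigurationError(f"unknown disease mode {self.disease_mode!r}")
        if not 0.0 < self.target_prevalence < 1.0:
            raise ConfigurationError("target_prevalence must lie in (0, 1)")
        if not 0.0 <= self.covariate_r2 < 1.0:
            raise ConfigurationError("covariate_r2 must lie in [0, 1)")


def _truth_eafs(panel: Panel) -> np.ndarray:
    eafs = np.array([np.nan if s.reference_eaf is None else s.reference_eaf
                     for s in panel.snps])
    if np.isnan(eafs).any():
        bad = [s.snp_id for s, e in zip(panel.snps, eafs) if np.isnan(e)]
        raise ValueError(f"panel SNPs lack an EAF to simulate from: {bad}")
    return eafs


def simulate_genotypes(panel: Panel, n: int, seed) -> GenotypeMatrix:
    """Draw an n × panel matrix of genotypes in HWE at the panel's EAFs.

    ``seed`` may be an int or a ``numpy.random.Generator``.  Individual ids
    are ``S0001``-style strings.
    """
    rng = np.random.default_rng(seed)
    eafs = _truth_eafs(panel)
    values = rng.binomial(2, eafs, size=(n, panel.size)).astype(float)
    ids = pd.Index([f"S{i+1:05d}" for i in range(n)], name="individual_id")
    return GenotypeMatrix(pd.DataFrame(values, index=ids, columns=panel.snp_ids))


def apply_missingness(matrix: GenotypeMatrix, missing_rate: float, seed) -> GenotypeMatrix:
    """Set each call missing independently with probability ``missing_rate``."""
    if not 0.0 <= missing_rate < 1.0:
        raise ConfigurationError("missing_rate must lie in [0, 1)")
    if missing_rate == 0.0:
        return GenotypeMatrix(matrix.df.copy())
    rng = np.random.default_rng(seed)
    mask = rng.random(matrix.df.shape) < missing_rate
    values = matrix.df.to_numpy(dtype=float).copy()
    values[mask] = np.nan
    return GenotypeMatrix(pd.DataFrame(values, index=matrix.df.index,
                                       columns=matrix.df.columns))


def simulate_covariates(n: int, seed) -> pd.DataFrame:
    """Draw age, sex, smoking and activity for n individuals."""
    rng = np.random.default_rng(seed)
    ids = pd.Index([f"S{i+1:05d}" for i in range(n)], name="individual_id")
    age = rng.uniform(*AGE_RANGE, size=n)
    sex = np.where(rng.random(n) < FEMALE_FRACTION, "female", "male")
    smoking = rng.choice(list(SMOKING_PROBS), size=n, p=list(SMOKING_PROBS.values()))
    activity = rng.choice(["none", "low", "medium", "high"], size=n)
    return pd.DataFrame({"age": age, "sex": sex, "smoking": smoking,
                         "activity": activity}, index=ids)


# Unit-scale covariate coefficients; the overall scale is solved in closed
# form from the covariates' theoretical means and variances so the combined
# score is centred with unit variance, and the share of BMI variance it
# carries is set exactly by the configuration.
_COV_DIRECTIONS = {"age": +1.0, "female": -1.0, "activity": -1.0, "current_smoker": +1.0}
_COV_MEANS = {
    "age": (AGE_RANGE[0] + AGE_RANGE[1]) / 2.0,
    "female": FEMALE_FRACTION,
    "activity": 1.5,  # uniform over {0,1,2,3}
    "current_smoker": SMOKING_PROBS["current"],
}
_COV_VARIANCES = {
    "age": (AGE_RANGE[1] - AGE_RANGE[0]) ** 2 / 12.0,
    "female": FEMALE_FRACTION * (1 - FEMALE_FRACTION),
    "activity": 1.25,
    "current_smoker": SMOKING_PROBS["current"] * (1 - SMOKING_PROBS["current"]),
}


def _covariate_score(covariates: pd.DataFrame) -> tuple[pd.Series, float]:
    """Centred, unit-variance covariate score.

    Each covariate enters standardised by its theoretical mean and SD with
    the documented sign convention (age raises BMI; being female and more
    activity lower it; current smoking raises it); the equally-weighted sum
    is rescaled by its theoretical SD, so under the generator's covariate
    distributions the returned score has mean 0 and variance 1.
    """
    parts = {
        "age": covariates["age"].astype(float),
        "female": (covariates["sex"] == "female").astype(float),
        "activity": covariates["activity"].map(
            {"none": 0, "low": 1, "medium": 2, "high": 3}).astype(float),
        "current_smoker": (covariates["smoking"] == "current").astype(float),
    }
    total = None
    for name, series in parts.items():
        z = _COV_DIRECTIONS[name] * (series - _COV_MEANS[name]) / np.sqrt(_COV_VARIANCES[name])
        total = z if total is None else total + z
    score = total / np.sqrt(float(len(parts)))  # independent unit-variance parts
    return score, 1.0


def panel_score_variance(panel: Panel) -> float:
    """Theoretical variance of the allele-unit score under HWE at the panel EAFs."""
    eafs = _truth_eafs(panel)
    u = rescale_score(np.array([s.weight for s in panel.snps]), panel)
    return float(np.sum(u**2 * 2 * eafs * (1 - eafs)))


def panel_score_mean(panel: Panel) -> float:
    """Theoretical mean of the allele-unit score under the panel EAFs."""
    eafs = _truth_eafs(panel)
    u = rescale_score(np.array([s.weight for s in panel.snps]), panel)
    return float(np.sum(u * 2 * eafs))


def simulate_bmi(gps_values: pd.Series, covariates: pd.DataFrame,
                 config: SimulationConfig, seed) -> pd.DataFrame:
    """BMI from the variance budget, plus consistent weight/height/waist/hip.

    BMI = mean + β·(GPS − E[GPS]) + c·Z + ε, with Z the unit-variance
    covariate score, c² = covariate_r2 · total variance, and ε Gaussian with
    whatever variance the budget leaves.  Raises if the genetic and
    covariate components already exceed the total.  Height is drawn by sex
    and weight back-derived so the Quetelet equation reproduces the
    simulated BMI exactly; waist and hip are driven by BMI alone (so their
    score associations are mediated by BMI by construction).
    """
    rng = np.random.default_rng(seed)
    gps = pd.Series(gps_values, dtype=float)
    total_var = config.bmi_total_sd**2
    genetic_var = config.bmi_per_allele**2 * panel_score_variance(config.panel)
    cov_var = config.covariate_r2 * total_var
    noise_var = total_var - genetic_var - cov_var
    if noise_var <= 0:
        raise ConfigurationError(
            f"variance budget infeasible: genetic {genetic_var:.2f} + covariates "
            f"{cov_var:.2f} exceed total {total_var:.2f}"
        )
    z, _ = _covariate_score(covariates.loc[gps.index])
    centred = gps - panel_score_mean(config.panel)
    bmi = (config.bmi_mean + config.bmi_per_allele * centred
           + np.sqrt(cov_var) * z + rng.normal(0.0, np.sqrt(noise_var), size=len(gps)))
    bmi = bmi.clip(lower=13.0)  # keep anthropometry physical in extreme tails

    female = (covariates.loc[gps.index, "sex"] == "female").to_numpy()
    height = np.where(female, rng.normal(1.61, 0.065, len(gps)),
                      rng.normal(1.72, 0.070, len(gps)))
    height = np.clip(height, 1.40, 2.10)
    weight = bmi.to_numpy() * height**2
    waist = 2.3 * bmi.to_numpy() + 22.0 + rng.normal(0.0, 4.0, len(gps))
    hip = 2.1 * bmi.to_numpy() + 42.0 + rng.normal(0.0, 3.5, len(gps))
    return pd.DataFrame({"bmi": bmi, "height": height, "weight": weight,
                         "waist": np.clip(waist, 50.0, None),
                         "hip": np.clip(hip, 60.0, None)}, index=gps.index)


def simulate_obesity(gps_values: pd.Series, covariates: pd.DataFrame,
                     config: SimulationConfig, seed,
                     bmi: pd.Series | None = None) -> pd.Series:
    """Case/control labels (1 = obese).

    threshold mode: labels are ``classify_bmi(bmi) == "obese"`` — supply the
    simulated BMI; overweight individuals are excluded downstream by the
    analysis, not here.  logistic mode: P(case) = expit(α + ln(OR)·(GPS −
    mean) + γ·Z), with α solved so the expected prevalence matches the
    target.
    """
    gps = pd.Series(gps_values, dtype=float)
    if config.disease_mode == "threshold":
        if bmi is None:
            raise ConfigurationError("threshold mode needs the simulated BMI")
        return pd.Series((classify_bmi(bmi) == "obese").astype(int),
                         index=gps.index, name="obese")
    rng = np.random.default_rng(seed)
    z, _ = _covariate_score(covariates.loc[gps.index])
    eta = (np.log(config.or_per_allele) * (gps - panel_score_mean(config.panel))
           + config.covariate_logodds_per_sd * z).to_numpy()

    def prevalence_gap(alpha: float) -> float:
        return float(special.expit(alpha + eta).mean()) - config.target_prevalence

    lo, hi = -30.0, 30.0
    if prevalence_gap(lo) > 0 or prevalence_gap(hi) < 0:
        raise ConfigurationError("target prevalence unreachable for this linear predictor")
    alpha = optimize.brentq(prevalence_gap, lo, hi, xtol=1e-10)
    labels = (rng.random(len(gps)) < special.expit(alpha + eta)).astype(int)
    return pd.Series(labels, index=gps.index, name="obese")


@dataclass(frozen=True)
class SimulatedCohort:
    """A complete simulated cohort plus the ground truth used to build it."""

    panel: Panel
    genotypes: GenotypeMatrix  # with missingness applied
    phenotypes: pd.DataFrame  # age..hip plus obese label column
    truth: dict = field(repr=False)


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Generate genotypes, covariates, BMI-consistent anthropometry and labels.

    Sub-seeds for each stage are spawned deterministically from
    ``config.seed``; identical configs give identical cohorts.
    """
    root = np.random.SeedSequence(config.seed)
    s_geno, s_miss, s_cov, s_bmi, s_dis = root.spawn(5)
    complete = simulate_genotypes(config.panel, config.n, np.random.default_rng(s_geno))
    covariates = simulate_covariates(config.n, np.random.default_rng(s_cov))

    # Truth score from complete genotypes: the per-allele effect acts on the
    # individual's actual allele load, before any missingness is observed.
    weights = np.array([s.weight for s in config.panel.snps])
    raw = complete.df.to_numpy() @ weights
    gps_true = pd.Series(rescale_score(raw, config.panel), index=complete.df.index,
                         name="gps_true")

    anthro = simulate_bmi(gps_true, covariates, config, np.random.default_rng(s_bmi))
    obese = simulate_obesity(gps_true, covariates, config, np.random.default_rng(s_dis),
                             bmi=anthro["bmi"])
    observed = apply_missingness(complete, config.missing_rate,
                                 np.random.default_rng(s_miss))
    phenotypes = covariates.join(anthro[["weight", "height", "waist", "hip"]])
    phenotypes["obese"] = obese
    truth = {
        "gps_true": gps_true,
        "bmi_true": anthro["bmi"],
        "config": config,
        "genotypes_complete": complete,
    }
    return SimulatedCohort(config.panel, observed, phenotypes, truth)


def default_config(seed: int = 0, **overrides) -> SimulationConfig:
    """The study-conditions configuration on the bundled simulation panel."""
    from .datasets import simulation_panel

    return replace(SimulationConfig(panel=simulation_panel(), seed=seed), **overrides)
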