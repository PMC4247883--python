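"""Covariate-adjusted association analyses.

Continuous anthropometric traits are analysed with ordinary least squares
under an additive genetic model (trait linear in allele count or score);
obesity risk with maximum-likelihood logistic regression.  Inference is Wald
throughout: 95% CIs are estimate ± 1.96·SE.  The module also provides the
score-quartile odds-ratio table with an ordinal trend test, the crude/full
explained-variance decomposition, and the exact binomial test of
direction-consistency of per-SNP effects against their discovery direction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .data_model import (
    ACTIVITY_LEVELS,
    GenotypeMatrix,
    NonConvergenceError,
    Panel,
    SingularDesignError,
)

Z975 = float(stats.norm.ppf(0.975))

#: Adjustment set used for BMI and obesity models.
DEFAULT_ADJUSTMENT = ("age", "sex", "activity", "smoking")
#: Additional adjustment for waist/hip models probing mediation by BMI.
BMI_ADJUSTMENT = DEFAULT_ADJUSTMENT + ("bmi",)


@dataclass(frozen=True)
class AssociationResult:
    outcome: str
    exposure: str
    model: str  # "linear" | "logistic"
    n: int
    estimate: float  # per-allele slope (linear) or log-OR (logistic)
    se: float
    lcl: float
    ucl: float
    p: float
    adjustment_set: tuple[str, ...]
    or_value: float | None = None
    r2_percent: float | None = None  # full-model R², linear only
    r2_crude_percent: float | None = None  # exposure-only R², linear only


def encode_covariates(covariates: pd.DataFrame, adjustment_set,
                      smoking_coding: str = "binary") -> pd.DataFrame:
    """Numeric design columns for the requested covariates.

    sex -> female indicator (male reference); activity -> ordinal 0-3
    (none/low/medium/high); smoking -> current-smoker indicator by default
    (``smoking_coding="levels"`` expands to current/former dummies with never
    as reference).  Numeric covariates (age, bmi, ...) pass through.
    """
    cols = {}
    for name in adjustment_set:
        if name not in covariates.columns:
            raise KeyError(f"covariate {name!r} not in phenotype table")
        col = covariates[name]
        if name == "sex":
            cols["female"] = (col == "female").astype(float)
        elif name == "activity":
            cols["activity"] = col.map({lvl: i for i, lvl in enumerate(ACTIVITY_LEVELS)}).astype(float)
        elif name == "smoking":
            if smoking_coding == "binary":
                cols["current_smoker"] = (col == "current").astype(float)
            elif smoking_coding == "levels":
                cols["current_smoker"] = (col == "current").astype(float)
                cols["former_smoker"] = (col == "former").astype(float)
            else:
                raise ValueError(f"unknown smoking coding {smoking_coding!r}")
        else:
            cols[name] = pd.to_numeric(col, errors="raise").astype(float)
    return pd.DataFrame(cols, index=covariates.index)


def _design(exposure: pd.Series, covariates: pd.DataFrame | None, adjustment_set,
            smoking_coding: str) -> pd.DataFrame:
    X = pd.DataFrame({"exposure": exposure.astype(float)})
    if adjustment_set:
        if covariates is None:
            raise ValueError("adjustment requested but no covariate table given")
        enc = encode_covariates(covariates, adjustment_set, smoking_coding)
        X = X.join(enc, how="inner")
    return sm.add_constant(X, has_constant="add")


def _check_rank(X: pd.DataFrame) -> None:
    arr = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(arr)
    if rank < arr.shape[1]:
        # name the columns whose removal restores full rank
        offending = []
        for j, col in enumerate(X.columns):
            reduced = np.delete(arr, j, axis=1)
            if np.linalg.matrix_rank(reduced) == rank:
                offending.append(col)
        raise SingularDesignError(f"design matrix is singular; offending columns: {offending}")


def _complete_cases(*frames):
    joined = pd.concat(frames, axis=1, join="inner")
    return joined.dropna().index


def fit_linear(outcome_values: pd.Series, exposure_values: pd.Series,
               covariates: pd.DataFrame | None = None, adjustment_set=(),
               outcome: str = "outcome", exposure: str = "exposure",
               smoking_coding: str = "binary") -> AssociationResult:
    """OLS association of a continuous trait with an allele count or score.

    Listwise deletion of incomplete cases; Wald CI and two-sided p for the
    exposure term.  Reports both the full-model R² and the crude
    (exposure-only) R² on the same analysis sample.
    """
    y = pd.Series(outcome_values, dtype=float)
    X = _design(pd.Series(exposure_values), covariates, adjustment_set, smoking_coding)
    idx = _complete_cases(y.rename("__y__"), X)
    y, X = y.loc[idx], X.loc[idx]
    if len(idx) <= X.shape[1]:
        raise ValueError(f"too few complete cases (n={len(idx)}) for {X.shape[1]} parameters")
    _check_rank(X)
    fit = sm.OLS(y, X).fit()
    est = float(fit.params["exposure"])
    se = float(fit.bse["exposure"])
    crude = sm.OLS(y, X[["const", "exposure"]]).fit()
    return AssociationResult(
        outcome=outcome, exposure=exposure, model="linear", n=int(fit.nobs),
        estimate=est, se=se, lcl=est - Z975 * se, ucl=est + Z975 * se,
        p=float(fit.pvalues["exposure"]), adjustment_set=tuple(adjustment_set),
        r2_percent=100 * float(fit.rsquared),
        r2_crude_percent=100 * float(crude.rsquared),
    )


def fit_logistic(case_status: pd.Series, exposure_values: pd.Series,
                 covariates: pd.DataFrame | None = None, adjustment_set=(),
                 outcome: str = "case", exposure: str = "exposure",
                 smoking_coding: str = "binary") -> AssociationResult:
    """Maximum-likelihood logistic association; per-allele OR with Wald 95% CI."""
    y = pd.Series(case_status).astype(float)
    if not set(y.dropna().unique()) <= {0.0, 1.0}:
        raise ValueError("case status must be binary 0/1")
    X = _design(pd.Series(exposure_values), covariates, adjustment_set, smoking_coding)
    idx = _complete_cases(y.rename("__y__"), X)
    y, X = y.loc[idx], X.loc[idx]
    if y.nunique() < 2:
        raise ValueError("both cases and controls are required")
    _check_rank(X)
    try:
        fit = sm.Logit(y, X).fit(disp=0, maxiter=100)
    except Exception as exc:  # statsmodels raises PerfectSeparationError and friends
        raise NonConvergenceError(f"logistic fit failed: {exc}") from exc
    if not fit.mle_retvals.get("converged", True):
        raise NonConvergenceError("logistic fit did not converge (possible separation)")
    est = float(fit.params["exposure"])
    se = float(fit.bse["exposure"])
    if not np.isfinite(se) or se > 1e3:
        raise NonConvergenceError("unstable logistic fit (exploding standard error)")
    return AssociationResult(
        outcome=outcome, exposure=exposure, model="logistic", n=int(fit.nobs),
        estimate=est, se=se, lcl=est - Z975 * se, ucl=est + Z975 * se,
        p=float(fit.pvalues["exposure"]), adjustment_set=tuple(adjustment_set),
        or_value=float(np.exp(est)),
    )


@dataclass(frozen=True)
class QuartileRow:
    quartile: int
    n_controls: int
    n_cases: int
    or_value: float | None  # None for an inestimable (empty-cell) row
    lcl: float | None
    ucl: float | None
    p: float | None


@dataclass(frozen=True)
class QuartileTable:
    rows: tuple[QuartileRow, ...]
    p_trend: float
    cut_points: tuple[float, float, float]
    adjustment_set: tuple[str, ...] = field(default=())

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame([r.__dict__ for r in self.rows]).set_index("quartile")
        df.attrs["p_trend"] = self.p_trend
        df.attrs["cut_points"] = self.cut_points
        return df


def quartile_or_analysis(gps: pd.Series, case_status: pd.Series,
                         covariates: pd.DataFrame | None = None,
                         adjustment_set=DEFAULT_ADJUSTMENT,
                         smoking_coding: str = "binary") -> QuartileTable:
    """Obesity risk per score quartile, with an ordinal trend test.

    Quartile cut points come from the analysis sample itself.  Quartiles 2-4
    enter an adjusted logistic model as indicators against quartile 1
    (reference, OR = 1); the trend p is from a second model with the quartile
    index entered as a single ordinal 0-3 term.  Callers analysing obesity
    must remove overweight individuals first (they are neither case nor
    control).
    """
    from .gps_score import assign_quartiles

    y = pd.Series(case_status).astype(float)
    g = pd.Series(gps, dtype=float)
    idx = _complete_cases(y.rename("__y__"), g.rename("__g__"))
    if covariates is not None and adjustment_set:
        enc = encode_covariates(covariates, adjustment_set, smoking_coding)
        idx = _complete_cases(y.loc[idx].rename("__y__"), enc.loc[idx.intersection(enc.index)])
    y, g = y.loc[idx], g.loc[idx]
    qa = assign_quartiles(g)
    labels = qa.labels

    cov_enc = None
    if covariates is not None and adjustment_set:
        cov_enc = encode_covariates(covariates, adjustment_set, smoking_coding).loc[idx]

    # A quartile with no cases or no controls has an undefined OR; its
    # individuals are dropped from the indicator model so the remaining
    # contrasts stay estimable, and its row is reported with OR = None.
    estimable = {k: int(((labels == k) & (y == 1)).sum()) > 0
                    and int(((labels == k) & (y == 0)).sum()) > 0
                 for k in (2, 3, 4)}
    keep = labels.isin([1] + [k for k in (2, 3, 4) if estimable[k]])
    X = pd.DataFrame({f"q{k}": (labels[keep] == k).astype(float)
                      for k in (2, 3, 4) if estimable[k]}, index=labels.index[keep])
    if cov_enc is not None:
        X = X.join(cov_enc.loc[keep])
    X = sm.add_constant(X, has_constant="add")
    try:
        fit = sm.Logit(y[keep], X).fit(disp=0, maxiter=100)
        converged = fit.mle_retvals.get("converged", True)
    except Exception:
        fit, converged = None, False

    rows = [QuartileRow(1, int(((labels == 1) & (y == 0)).sum()),
                        int(((labels == 1) & (y == 1)).sum()), 1.0, None, None, None)]
    for k in (2, 3, 4):
        n_ctrl = int(((labels == k) & (y == 0)).sum())
        n_case = int(((labels == k) & (y == 1)).sum())
        if fit is not None and converged and estimable[k]:
            est, se = float(fit.params[f"q{k}"]), float(fit.bse[f"q{k}"])
            rows.append(QuartileRow(k, n_ctrl, n_case, float(np.exp(est)),
                                    float(np.exp(est - Z975 * se)),
                                    float(np.exp(est + Z975 * se)),
                                    float(fit.pvalues[f"q{k}"])))
        else:
            rows.append(QuartileRow(k, n_ctrl, n_case, None, None, None, None))

    Xt = pd.DataFrame({"trend": (labels - 1).astype(float)}, index=idx)
    if cov_enc is not None:
        Xt = Xt.join(cov_enc)
    Xt = sm.add_constant(Xt, has_constant="add")
    try:
        trend_fit = sm.Logit(y, Xt).fit(disp=0, maxiter=100)
        p_trend = float(trend_fit.pvalues["trend"])
    except Exception as exc:
        raise NonConvergenceError(f"trend model failed: {exc}") from exc
    return QuartileTable(tuple(rows), p_trend, qa.cut_points, tuple(adjustment_set))


def explained_variance_decomposition(outcome: pd.Series, gps: pd.Series,
                                     covariates: pd.DataFrame,
                                     adjustment_set=DEFAULT_ADJUSTMENT,
                                     smoking_coding: str = "binary"):
    """Percent of trait variance from the score alone, the full model, and covariates.

    ``r2_crude`` is the R² of trait ~ score, ``r2_full`` of trait ~ score +
    covariates (same complete-case sample), and ``r2_covariables`` their
    difference — the increment attributable to the covariates.
    """
    res = fit_linear(outcome, gps, covariates, adjustment_set,
                     smoking_coding=smoking_coding)
    r2_crude = res.r2_crude_percent
    r2_full = res.r2_percent
    return r2_crude, r2_full, r2_full - r2_crude


def direction_consistency(observed_betas, reference_directions=None):
    """Exact binomial test of effect-direction agreement with discovery GWAS.

    With effect alleles oriented so every reference direction is positive, an
    observed beta agrees when it is strictly positive (an exact zero counts
    as inconsistent).  Returns ``(k_consistent, n, p)`` with the one-sided
    exact tail p = P(X >= k | n, 1/2).
    """
    betas = np.asarray(observed_betas, dtype=float)
    if reference_directions is None:
        ref = np.ones_like(betas)
    else:
        ref = np.sign(np.asarray(reference_directions, dtype=float))
        if np.any(ref == 0):
            raise ValueError("reference directions must be non-zero")
    n = betas.size
    k = int(np.sum(np.sign(betas) == ref))
    p = float(stats.binom.sf(k - 1, n, 0.5))
    return k, n, p


def direction_consistency_normal_approx(k: int, n: int) -> float:
    """One-sided normal approximation to the binomial tail, no continuity correction."""
    z = (k - n / 2) / np.sqrt(n / 4)
    return float(stats.norm.sf(z))


def per_snp_associations(matrix: GenotypeMatrix, phenotypes: pd.DataFrame, panel: Panel,
                         outcome: str = "bmi", adjustment_set=DEFAULT_ADJUSTMENT,
                         alpha: float = 0.05, smoking_coding: str = "binary") -> pd.DataFrame:
    """Additive-model association of each panel SNP with a trait.

    One OLS fit per SNP with the coded genotype as exposure, under the same
    adjustment set as the score analyses; the significance flag uses the
    Bonferroni threshold alpha / (number of SNPs tested).
    """
    from .snp_qc import bonferroni_threshold

    threshold = bonferroni_threshold(alpha, panel.size)
    rows = []
    for snp in panel.snps:
        res = fit_linear(phenotypes[outcome], matrix.column(snp.snp_id),
                         phenotypes, adjustment_set, outcome=outcome,
                         exposure=snp.snp_id, smoking_coding=smoking_coding)
        rows.append({
            "snp_id": snp.snp_id, "locus": snp.locus_label, "n": res.n,
            "beta": res.estimate, "se": res.se, "lcl": res.lcl, "ucl": res.ucl,
            "p": res.p, "significant": res.p <= threshold,
        })
    out = pd.DataFrame(rows).set_index("snp_id")
    out.attrs["bonferroni_threshold"] = threshold
    return out
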