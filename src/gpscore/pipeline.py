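"""End-to-end orchestration: QC → score → associations → report bundle.

``run_pipeline`` takes one :class:`RunConfig` and writes a bundle of
tab-separated tables (QC report, per-individual scores, trait associations
under both adjustment sets, variance decomposition, obesity quartile table,
per-SNP associations, direction-consistency summary) plus a JSON run log.
When a SNP exclusion list is configured, the whole analysis is rerun on the
reduced panel with the score renormalised to its new allele range, mirroring
a leave-out sensitivity analysis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as gio
from .association import (
    BMI_ADJUSTMENT,
    DEFAULT_ADJUSTMENT,
    direction_consistency,
    explained_variance_decomposition,
    fit_linear,
    fit_logistic,
    per_snp_associations,
    quartile_or_analysis,
)
from .data_model import GenotypeMatrix, Panel
from .gps_score import assign_quartiles, compute_scores
from .snp_qc import qc_report
from .synthetic_cohort import SimulationConfig, simulate_cohort

#: Default leave-out list: the four panel SNPs whose HWE p-values sat just
#: above the Bonferroni threshold in the emulated cohort (4.0e-3 to 8.4e-3).
DEFAULT_SENSITIVITY_EXCLUSION = ("rs3817334", "rs987237", "rs10968576", "rs4929949")

CONTINUOUS_TRAITS = ("bmi", "waist", "hip", "whr")


@dataclass(frozen=True)
class RunConfig:
    panel_path: str | None = None
    genotype_path: str | None = None
    phenotype_path: str | None = None
    weights_path: str | None = None
    format_hint: str | None = None
    simulation: SimulationConfig | None = None
    out_dir: str = "results/run"
    min_call_rate: float = 0.95
    max_missing: int = 3
    alpha: float = 0.05
    smoking_coding: str = "binary"
    snp_exclusion_list: tuple[str, ...] = DEFAULT_SENSITIVITY_EXCLUSION
    seed: int = 0


def _round_mixed(df: pd.DataFrame, two_dp=(), four_dp=()) -> pd.DataFrame:
    disp = df.copy()
    for c in two_dp:
        if c in disp.columns:
            disp[c] = disp[c].astype(float).round(2)
    for c in four_dp:
        if c in disp.columns:
            disp[c] = disp[c].astype(float).round(4)
    return disp


def _analyse_panel(panel: Panel, genotypes: GenotypeMatrix, phenotypes: pd.DataFrame,
                   config: RunConfig, out_dir: Path, log: dict) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)

    qc = qc_report(genotypes, panel, alpha=config.alpha, min_rate=config.min_call_rate)
    qc.to_csv(out_dir / "qc_report.tsv", sep="\t")
    _round_mixed(qc, two_dp=("eaf", "oaf"), four_dp=("hwe_p", "freq_diff_p")).to_csv(
        out_dir / "qc_report_display.tsv", sep="\t")
    kept_ids = qc.index[qc["kept"]].tolist()
    log["snps_dropped_call_rate"] = qc.attrs["dropped_call_rate"]
    log["bonferroni_threshold"] = qc.attrs["bonferroni_threshold"]
    if not kept_ids:
        raise ValueError("no SNPs survive the call-rate filter")
    scored_panel = panel.subset(keep=kept_ids, name=f"{panel.name}_qc")

    scores = compute_scores(genotypes, scored_panel, max_missing=config.max_missing)
    analysed = scores.index[~scores["excluded"]]
    log["n_excluded_high_missing"] = int(scores["excluded"].sum())
    log["n_scored"] = int(len(analysed))

    data = phenotypes.loc[phenotypes.index.intersection(analysed)]
    gps = scores.loc[data.index, "gps"]
    quart = assign_quartiles(gps)
    score_table = scores.copy()
    score_table["quartile"] = quart.labels.reindex(scores.index)
    score_table.to_csv(out_dir / "scores.tsv", sep="\t")
    log["gps_mean"] = float(gps.mean())
    log["gps_sd"] = float(gps.std(ddof=1))
    log["quartile_cuts"] = list(quart.cut_points)

    # Trait associations (Table 2 analogue): primary adjustment set for all
    # four traits, plus the BMI-added set for the central-adiposity traits.
    rows = []
    for trait in CONTINUOUS_TRAITS:
        res = fit_linear(data[trait], gps, data, DEFAULT_ADJUSTMENT, outcome=trait,
                         exposure="gps", smoking_coding=config.smoking_coding)
        rows.append(res.__dict__ | {"adjustment": "primary"})
        if trait in ("waist", "hip", "whr"):
            res_b = fit_linear(data[trait], gps, data, BMI_ADJUSTMENT, outcome=trait,
                               exposure="gps", smoking_coding=config.smoking_coding)
            rows.append(res_b.__dict__ | {"adjustment": "plus_bmi"})
    assoc = pd.DataFrame(rows).drop(columns=["adjustment_set"])
    assoc.to_csv(out_dir / "trait_associations.tsv", sep="\t", index=False)
    _round_mixed(assoc, two_dp=("estimate", "se", "lcl", "ucl"), four_dp=("p",)).to_csv(
        out_dir / "trait_associations_display.tsv", sep="\t", index=False)

    r2_crude, r2_full, r2_cov = explained_variance_decomposition(
        data["bmi"], gps, data, DEFAULT_ADJUSTMENT, smoking_coding=config.smoking_coding)
    pd.DataFrame(
        [{"component": "score_alone", "r2_percent": r2_crude},
         {"component": "score_plus_covariables", "r2_percent": r2_full},
         {"component": "covariables_increment", "r2_percent": r2_cov}]
    ).to_csv(out_dir / "variance_decomposition.tsv", sep="\t", index=False)

    # Obesity analyses exclude overweight individuals: they are neither
    # normal-weight controls nor obese cases.
    if "obese" in data.columns and data["obese"].notna().any():
        case = data["obese"].astype(float)
    else:
        case = (data["bmi_class"] == "obese").astype(float)
    non_ow = data.index[data["bmi_class"] != "overweight"]
    log["n_overweight_removed"] = int(len(data.index) - len(non_ow))
    sub = data.loc[non_ow]
    case_sub = case.loc[non_ow]
    if case_sub.nunique() == 2:
        res_ob = fit_logistic(case_sub, gps.loc[non_ow], sub, DEFAULT_ADJUSTMENT,
                              outcome="obese", exposure="gps",
                              smoking_coding=config.smoking_coding)
        pd.DataFrame([res_ob.__dict__]).drop(columns=["adjustment_set"]).to_csv(
            out_dir / "obesity_association.tsv", sep="\t", index=False)
        qt = quartile_or_analysis(gps.loc[non_ow], case_sub, sub, DEFAULT_ADJUSTMENT,
                                  smoking_coding=config.smoking_coding)
        qframe = qt.to_frame()
        qframe["p_trend"] = qt.p_trend
        qframe.to_csv(out_dir / "quartile_obesity.tsv", sep="\t")
        log["p_trend"] = qt.p_trend
        log["or_per_allele"] = res_ob.or_value

    per_snp = per_snp_associations(genotypes.subset_individuals(list(data.index)),
                                   data, scored_panel, outcome="bmi",
                                   alpha=config.alpha,
                                   smoking_coding=config.smoking_coding)
    per_snp.to_csv(out_dir / "per_snp_associations.tsv", sep="\t")
    k, n, p = direction_consistency(per_snp["beta"].to_numpy())
    pd.DataFrame([{"k_consistent": k, "n_snps": n, "p_one_sided_exact": p}]).to_csv(
        out_dir / "direction_consistency.tsv", sep="\t", index=False)
    log["direction_consistency"] = {"k": k, "n": n, "p": p}


def run_pipeline(config: RunConfig) -> dict:
    """Run QC, scoring and all association analyses; write the report bundle.

    Returns the machine-readable run log (also saved as ``run_log.json``).
    With a simulation block the cohort is generated in place of file inputs;
    otherwise panel/genotype/phenotype paths are loaded and aligned.
    """
    out_dir = Path(config.out_dir)
    log: dict = {"seed": config.seed, "min_call_rate": config.min_call_rate,
                 "max_missing": config.max_missing, "alpha": config.alpha}

    if config.simulation is not None:
        cohort = simulate_cohort(config.simulation)
        panel, genotypes = cohort.panel, cohort.genotypes
        from .data_model import derive_anthropometrics
        phen = derive_anthropometrics(cohort.phenotypes.drop(columns=["obese"]))
        phen["obese"] = cohort.phenotypes["obese"]
        phenotypes = phen
        log["input"] = {"mode": "simulation", "n": config.simulation.n,
                        "seed": config.simulation.seed,
                        "disease_mode": config.simulation.disease_mode}
    else:
        if not (config.panel_path and config.genotype_path and config.phenotype_path):
            raise ValueError("either a simulation block or all three input paths are required")
        panel, genotypes, phenotypes, report = gio.load_inputs(
            config.panel_path, config.genotype_path, config.phenotype_path,
            format_hint=config.format_hint, weights_path=config.weights_path)
        log["input"] = {"mode": "files"} | report

    _analyse_panel(panel, genotypes, phenotypes, config, out_dir, log)

    if config.snp_exclusion_list:
        excl = [s for s in config.snp_exclusion_list if s in panel]
        log["sensitivity_excluded_snps"] = excl
        if excl:
            reduced = panel.subset(exclude=excl, name=f"{panel.name}_sens")
            sens_log: dict = {}
            _analyse_panel(reduced, genotypes.subset_snps(reduced.snp_ids), phenotypes,
                           config, out_dir / "sensitivity", sens_log)
            log["sensitivity"] = sens_log

    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        raise TypeError(type(o))

    (out_dir / "run_log.json").write_text(json.dumps(log, indent=2, default=_default))
    return log
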