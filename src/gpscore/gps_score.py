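"""Weighted genetic predisposition score (GPS) construction.

The score for an individual is the sum over panel SNPs of the published
per-allele weight times the coded effect-allele count, with missing genotypes
mean-imputed (replaced by the sample mean allele count of that SNP, i.e.
2×EAF).  The raw weighted score, bounded by twice the weight sum, is rescaled
to allele units — raw / (2 Σβ) × 2m for an m-SNP panel — so one score point
corresponds to one risk allele and the maximum is 2m (58 for a 29-SNP
panel).  Individuals missing more than ``max_missing`` genotypes are flagged
and excluded from downstream analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import GenotypeMatrix, Panel

DEFAULT_MAX_MISSING = 3


def mean_allele_count(matrix: GenotypeMatrix, snp_id: str) -> float:
    """Sample mean of the non-missing coded genotypes of one SNP (= 2×EAF)."""
    col = matrix.column(snp_id).dropna()
    if col.empty:
        raise ValueError(
            f"{snp_id}: every call missing; the SNP should have been removed by call-rate QC"
        )
    return float(col.mean())


def imputation_means(matrix: GenotypeMatrix) -> pd.Series:
    """Mean allele count per SNP, computed on the full genotyped sample."""
    return pd.Series({s: mean_allele_count(matrix, s) for s in matrix.snp_ids},
                     name="mean_allele_count")


def exclude_high_missing(matrix: GenotypeMatrix, max_missing: int = DEFAULT_MAX_MISSING):
    """Split individuals into kept (<= max_missing missing SNPs) and excluded."""
    n_missing = matrix.n_missing_per_individual()
    kept = n_missing.index[n_missing <= max_missing].tolist()
    excluded = n_missing.index[n_missing > max_missing].tolist()
    return kept, excluded


def weighted_score(genotype_row: pd.Series, panel: Panel, imputation_means: pd.Series) -> float:
    """Raw weighted score Σ β_i g_i of one individual, mean-imputing missing cells."""
    total = 0.0
    for snp in panel.snps:
        g = genotype_row[snp.snp_id]
        if np.isnan(g):
            if snp.snp_id not in imputation_means.index or np.isnan(imputation_means[snp.snp_id]):
                raise ValueError(f"no imputation mean available for {snp.snp_id}")
            g = imputation_means[snp.snp_id]
        total += snp.weight * g
    return float(total)


def rescale_score(raw_score, panel: Panel):
    """Rescale a raw weighted score to allele units: raw / (2 Σβ) × 2m.

    For the 29-SNP BMI panel this is the published "divide by 8.24, multiply
    by 58" transformation; stated generally it renormalises any sub-panel
    (e.g. a 25-SNP sensitivity rerun rescales onto a 0-50 range).
    """
    if panel.weight_sum <= 0:
        raise ValueError("panel weight sum must be positive")
    factor = (2 * panel.size) / (2 * panel.weight_sum)
    out = np.asarray(raw_score, dtype=float) * factor
    return float(out) if out.ndim == 0 else out


def compute_scores(matrix: GenotypeMatrix, panel: Panel,
                   max_missing: int = DEFAULT_MAX_MISSING,
                   means: pd.Series | None = None) -> pd.DataFrame:
    """Score every individual against the panel.

    Imputation means default to the full-sample means of ``matrix`` and are
    computed before the high-missingness exclusion (pass ``means`` to impose
    a different convention or external frequencies).  Returns a table with
    ``n_missing``, ``excluded``, ``raw_score`` and the allele-unit ``gps``;
    excluded individuals are still scored for inspection but flagged.
    """
    sub = matrix.subset_snps(panel.snp_ids)
    if means is None:
        means = imputation_means(sub)
    values = sub.df.to_numpy(dtype=float)
    fill = means.reindex(panel.snp_ids).to_numpy(dtype=float)
    if np.isnan(values).any(axis=0).any() and np.isnan(fill).any():
        bad = [s for s, f in zip(panel.snp_ids, fill) if np.isnan(f)]
        raise ValueError(f"no imputation mean available for {bad}")
    imputed = np.where(np.isnan(values), fill, values)
    weights = panel.weights.reindex(panel.snp_ids).to_numpy(dtype=float)
    raw = imputed @ weights
    n_missing = np.isnan(values).sum(axis=1)
    out = pd.DataFrame(
        {
            "n_missing": n_missing.astype(int),
            "excluded": n_missing > max_missing,
            "raw_score": raw,
            "gps": rescale_score(raw, panel),
        },
        index=sub.df.index,
    )
    out.attrs["max_missing"] = max_missing
    return out


@dataclass(frozen=True)
class QuartileAssignment:
    """Empirical score quartiles: three cut points and a 1-4 label per individual."""

    cut_points: tuple[float, float, float]
    labels: pd.Series  # int in {1,2,3,4}, indexed like the input

    def counts(self) -> pd.Series:
        return self.labels.value_counts().sort_index()


def assign_quartiles(gps_values: pd.Series) -> QuartileAssignment:
    """Assign score quartiles from the empirical 25/50/75 percentiles.

    Intervals are half-open with the top quartile closed above; a value
    exactly at a cut point goes to the upper quartile.  Requires at least
    four distinct values so the cut points are strictly increasing.
    """
    values = pd.Series(gps_values, dtype=float)
    if values.isna().any():
        raise ValueError("cannot assign quartiles with missing scores")
    cuts = np.quantile(values.to_numpy(), [0.25, 0.5, 0.75])
    if not (cuts[0] < cuts[1] < cuts[2]):
        raise ValueError("quartile cut points are not strictly increasing "
                         "(need at least four distinct, spread-out score values)")
    labels = pd.Series(np.searchsorted(cuts, values.to_numpy(), side="right") + 1,
                       index=values.index, name="quartile")
    return QuartileAssignment((float(cuts[0]), float(cuts[1]), float(cuts[2])), labels)
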