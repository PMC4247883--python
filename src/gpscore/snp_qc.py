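"""Per-SNP quality control.

Genotype counts, effect-allele frequency, Hardy-Weinberg testing (Pearson
1-df χ² by default, an exact conditional test as an opt-in alternative),
call-rate filtering, and a goodness-of-fit comparison of observed allele
frequencies against a reference population, with Bonferroni-corrected flags.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import GenotypeMatrix, Panel

DEFAULT_MIN_CALL_RATE = 0.95


@dataclass(frozen=True)
class HweResult:
    """Genotype counts with the Hardy-Weinberg goodness-of-fit statistic."""

    snp_id: str
    counts: tuple[int, int, int]
    eaf: float
    chi2: float
    p: float
    df: int = 1

    @property
    def n(self) -> int:
        return sum(self.counts)


def genotype_counts(matrix: GenotypeMatrix, snp_id: str) -> tuple[int, int, int]:
    """Counts of individuals carrying 0, 1 and 2 effect alleles (non-missing only)."""
    col = matrix.column(snp_id).dropna().to_numpy()
    return (int((col == 0).sum()), int((col == 1).sum()), int((col == 2).sum()))


def effect_allele_frequency(counts) -> float:
    """EAF from genotype counts: (n1 + 2 n2) / 2n."""
    n0, n1, n2 = counts
    n = n0 + n1 + n2
    if n == 0:
        raise ValueError("allele frequency undefined for zero genotype calls")
    return (n1 + 2 * n2) / (2 * n)


def hwe_chi2(counts, snp_id: str = "") -> HweResult:
    """Pearson 1-df goodness-of-fit test of Hardy-Weinberg proportions.

    Expected counts are n(1-f)², 2nf(1-f), nf² with f the sample EAF; no
    continuity correction.  A monomorphic SNP (f in {0, 1}) has no measurable
    departure and returns chi2 = 0, p = 1 by convention.
    """
    n0, n1, n2 = counts
    if min(n0, n1, n2) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n0 + n1 + n2
    f = effect_allele_frequency(counts)
    if f in (0.0, 1.0):
        return HweResult(snp_id, (n0, n1, n2), f, 0.0, 1.0)
    expected = np.array([n * (1 - f) ** 2, n * 2 * f * (1 - f), n * f**2])
    observed = np.array([n0, n1, n2], dtype=float)
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    p = float(stats.chi2.sf(chi2, 1))
    return HweResult(snp_id, (n0, n1, n2), f, chi2, p)


def hwe_exact(counts) -> float:
    """Exact conditional Hardy-Weinberg test (Wigginton-style).

    Conditions on the observed allele counts and sums the probabilities of
    all heterozygote counts no more probable than the observed one.  More
    faithful than the χ² approximation for rare alleles.
    """
    n0, n1, n2 = counts
    if min(n0, n1, n2) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n0 + n1 + n2
    if n == 0:
        raise ValueError("exact test undefined for zero genotype calls")
    rare = min(n1 + 2 * n0, n1 + 2 * n2)  # copies of the rarer allele
    if rare == 0:
        return 1.0
    # Unnormalised probabilities over all heterozygote counts with the
    # observed parity, via the standard upward/downward recurrence.
    het_probs = np.zeros(rare + 1)
    mid = rare * (2 * n - rare) // (2 * n)
    if mid % 2 != rare % 2:
        mid += 1
    het_probs[mid] = 1.0
    # downward: P(h-2) = P(h) * h(h-1) / (4 * hom_r(h) + 1)(hom_c(h) + 1) form
    h = mid
    hom_r = (rare - mid) // 2
    hom_c = n - mid - hom_r
    while h > 1:
        het_probs[h - 2] = het_probs[h] * h * (h - 1) / (4.0 * (hom_r + 1) * (hom_c + 1))
        h -= 2
        hom_r += 1
        hom_c += 1
    h = mid
    hom_r = (rare - mid) // 2
    hom_c = n - mid - hom_r
    while h <= rare - 2:
        het_probs[h + 2] = het_probs[h] * 4.0 * hom_r * hom_c / ((h + 2.0) * (h + 1.0))
        h += 2
        hom_r -= 1
        hom_c -= 1
    het_probs /= het_probs.sum()
    p_obs = het_probs[n1]
    return float(min(1.0, het_probs[het_probs <= p_obs + 1e-12 * p_obs].sum()))


def call_rate_filter(matrix: GenotypeMatrix, panel: Panel,
                     min_rate: float = DEFAULT_MIN_CALL_RATE):
    """Split panel SNPs into kept (call rate >= min_rate) and dropped.

    Returns ``(kept_snp_ids, dropped)`` with ``dropped`` a dict of
    snp_id -> call rate.  The threshold is inclusive: a SNP at exactly
    ``min_rate`` is kept.
    """
    rates = matrix.call_rate()
    kept, dropped = [], {}
    for snp_id in panel.snp_ids:
        rate = float(rates.get(snp_id, 0.0))
        if rate >= min_rate:
            kept.append(snp_id)
        else:
            dropped[snp_id] = rate
    return kept, dropped


def compare_allele_distribution(counts, reference_eaf: float):
    """χ² goodness-of-fit of observed allele counts against a reference EAF.

    The 2n observed alleles are compared with expected proportions
    (reference_eaf, 1 - reference_eaf); 1 degree of freedom.  Reference
    sample counts are not used (not generally available), so this treats the
    reference frequency as fixed.
    """
    if not 0.0 < reference_eaf < 1.0:
        raise ValueError("reference EAF must lie strictly inside (0, 1)")
    n0, n1, n2 = counts
    n = n0 + n1 + n2
    if n == 0:
        raise ValueError("no genotype calls to compare")
    eff = n1 + 2 * n2
    oth = 2 * n - eff
    expected = np.array([2 * n * reference_eaf, 2 * n * (1 - reference_eaf)])
    observed = np.array([eff, oth], dtype=float)
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    return chi2, float(stats.chi2.sf(chi2, 1))


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Per-test significance threshold alpha / m."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    if m < 1:
        raise ValueError("m must be at least 1")
    return alpha / m


def qc_report(matrix: GenotypeMatrix, panel: Panel, alpha: float = 0.05,
              min_rate: float = DEFAULT_MIN_CALL_RATE, exact: bool = False) -> pd.DataFrame:
    """Per-SNP QC table: counts, EAF, HWE p, call rate, reference comparison, flags.

    The Bonferroni threshold uses m = number of SNPs surviving the call-rate
    filter.  ``exact=True`` switches the HWE p-value to the exact conditional
    test; the default is the Pearson χ².
    """
    kept, dropped = call_rate_filter(matrix, panel, min_rate=min_rate)
    m = max(len(kept), 1)
    threshold = bonferroni_threshold(alpha, m)
    rates = matrix.call_rate()
    rows = []
    for snp in panel.snps:
        counts = genotype_counts(matrix, snp.snp_id)
        n = sum(counts)
        eaf = effect_allele_frequency(counts) if n else np.nan
        if n:
            hwe_p = hwe_exact(counts) if exact else hwe_chi2(counts, snp.snp_id).p
        else:
            hwe_p = np.nan
        if snp.reference_eaf is not None and n and 0.0 < snp.reference_eaf < 1.0:
            _, freq_p = compare_allele_distribution(counts, snp.reference_eaf)
        else:
            freq_p = np.nan
        rows.append({
            "snp_id": snp.snp_id,
            "locus": snp.locus_label,
            "effect_allele": snp.effect_allele,
            "other_allele": snp.other_allele,
            "n0": counts[0], "n1": counts[1], "n2": counts[2],
            "eaf": eaf,
            "oaf": 1 - eaf if n else np.nan,
            "ref_eaf": snp.reference_eaf,
            "hwe_p": hwe_p,
            "call_rate": float(rates.get(snp.snp_id, 0.0)),
            "kept": snp.snp_id in set(kept),
            "hwe_flag": bool(n and hwe_p <= threshold),
            "freq_diff_p": freq_p,
            "freq_diff_flag": bool(np.isfinite(freq_p) and freq_p <= threshold),
        })
    report = pd.DataFrame(rows).set_index("snp_id")
    report.attrs["bonferroni_threshold"] = threshold
    report.attrs["n_tested"] = m
    report.attrs["dropped_call_rate"] = dropped
    return report
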