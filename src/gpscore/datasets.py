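"""Bundled example panel and cohort summary data.

The package ships the 29-SNP panel of BMI loci established by European
genome-wide association studies, together with the genotype distributions
those SNPs showed in a published North African (Algerian) urban cohort of 787
adults.  Three small tab-separated files back this module:

``example_panel.tsv``
    SNP ids, nearby locus, effect/other alleles and the European-reference
    effect-allele frequencies.  The ``weight`` column is NA: the per-allele
    β weights of the original GWAS are not redistributable here and must be
    supplied by the user.
``synthetic_weights.tsv``
    SYNTHETIC stand-in weights with a GWAS-like spread, constrained so the
    29 weights sum to 4.12 kg/m² (twice the sum, 8.24, is the maximum raw
    score of the panel, matching the published rescaling constant).  They are
    for simulation, testing and demonstration — not published effect sizes.
``cohort_genotype_counts.tsv``
    Observed genotype counts (0/1/2 effect-allele copies) per SNP in the
    cohort; these imply the cohort effect-allele frequencies used as truth by
    the synthetic-cohort generator.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .data_model import Panel, SnpDef
from . import io as _io


def _data_path(filename: str):
    return resources.files("gpscore.data").joinpath(filename)


def example_panel(with_weights: bool = True) -> Panel:
    """The bundled 29-SNP BMI panel.

    With ``with_weights=True`` (default) the synthetic stand-in weights are
    attached; with ``False`` loading fails unless you only need alleles and
    frequencies, so instead use :func:`example_panel_frame`.
    """
    with resources.as_file(_data_path("example_panel.tsv")) as panel_path:
        if with_weights:
            with resources.as_file(_data_path("synthetic_weights.tsv")) as wpath:
                return _io.read_panel(panel_path, weights_path=wpath, name="bmi29")
        return _io.read_panel(panel_path, name="bmi29")


def example_panel_frame() -> pd.DataFrame:
    """The raw panel table (weights NA) as a DataFrame."""
    with resources.as_file(_data_path("example_panel.tsv")) as p:
        return pd.read_csv(p, sep="\t", na_values=["NA"])


def cohort_genotype_counts() -> pd.DataFrame:
    """Observed per-SNP genotype counts in the Algerian cohort, indexed by snp_id."""
    with resources.as_file(_data_path("cohort_genotype_counts.tsv")) as p:
        return pd.read_csv(p, sep="\t", index_col="snp_id")


def cohort_eafs() -> pd.Series:
    """Cohort effect-allele frequencies implied by the bundled genotype counts."""
    c = cohort_genotype_counts()
    n = c.sum(axis=1)
    return ((c["n1"] + 2 * c["n2"]) / (2 * n)).rename("eaf")


def simulation_panel() -> Panel:
    """Panel used as ground truth by the synthetic-cohort generator.

    Same SNPs and synthetic weights as :func:`example_panel`, but with
    ``reference_eaf`` set to the cohort allele frequencies so simulated
    genotypes are drawn in Hardy-Weinberg proportions at the frequencies the
    cohort actually showed.
    """
    eafs = cohort_eafs()
    base = example_panel(with_weights=True)
    snps = tuple(
        SnpDef(s.snp_id, s.locus_label, s.effect_allele, s.other_allele,
               s.weight, reference_eaf=float(eafs[s.snp_id]))
        for s in base.snps
    )
    return Panel(snps, name="bmi29_sim")
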