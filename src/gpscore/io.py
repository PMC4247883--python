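"""Readers and writers for the panel, genotype and phenotype file formats.

Genotypes travel either in a simple tab-separated dialect (first column
``individual_id``, one column per SNP, cells in {0,1,2,NA}) or in plain VCF
4.x with GT fields.  VCF genotypes are re-oriented to effect-allele counts
using the panel: the panel is authoritative, REF/ALT polarity is resolved per
record, and strand flips are never guessed — a record whose allele pair does
not match the panel's raises :class:`AlleleMismatchError`.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .data_model import (
    MISSING_TOKENS,
    AlleleMismatchError,
    DuplicateIdError,
    GenotypeFormatError,
    GenotypeMatrix,
    Panel,
    PHENOTYPE_COLUMNS,
    SnpDef,
    derive_anthropometrics,
)

PANEL_COLUMNS = ["snp_id", "locus", "effect_allele", "other_allele", "weight", "ref_eaf"]


def read_panel(path, weights_path=None, name: str | None = None) -> Panel:
    """Read a tab-separated SNP panel file.

    The ``weight`` column may be NA when a separate two-column weights file
    (``snp_id``, ``weight``) is supplied via ``weights_path``; a panel whose
    weights cannot be resolved raises, because a weighted score is undefined
    without them.
    """
    df = pd.read_csv(path, sep="\t", dtype={"snp_id": str}, na_values=["NA"])
    missing_cols = [c for c in PANEL_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"panel file lacks columns: {missing_cols}")
    if weights_path is not None:
        w = pd.read_csv(weights_path, sep="\t", dtype={"snp_id": str})
        df = df.drop(columns="weight").merge(w[["snp_id", "weight"]], on="snp_id", how="left")
    if df["weight"].isna().any():
        bad = df.loc[df["weight"].isna(), "snp_id"].tolist()
        raise ValueError(f"no weight available for SNPs: {bad}")
    snps = tuple(
        SnpDef(
            snp_id=row.snp_id,
            locus_label=row.locus,
            effect_allele=row.effect_allele,
            other_allele=row.other_allele,
            weight=float(row.weight),
            reference_eaf=None if pd.isna(row.ref_eaf) else float(row.ref_eaf),
        )
        for row in df.itertuples()
    )
    return Panel(snps, name=name or Path(path).stem)


def write_panel(panel: Panel, path) -> None:
    rows = [
        {
            "snp_id": s.snp_id,
            "locus": s.locus_label,
            "effect_allele": s.effect_allele,
            "other_allele": s.other_allele,
            "weight": s.weight,
            "ref_eaf": "NA" if s.reference_eaf is None else s.reference_eaf,
        }
        for s in panel.snps
    ]
    pd.DataFrame(rows, columns=PANEL_COLUMNS).to_csv(path, sep="\t", index=False)


def _parse_genotype_cell(token: str, individual: str, snp: str) -> float:
    token = token.strip()
    if token in MISSING_TOKENS:
        return math.nan
    if token in {"0", "1", "2"}:
        return float(token)
    raise GenotypeFormatError(
        f"unknown genotype code {token!r} for individual {individual!r} at SNP {snp!r}"
    )


def read_genotypes_tsv(path) -> GenotypeMatrix:
    """Read the tab-separated genotype dialect into a matrix of dosages."""
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if raw.columns[0] != "individual_id":
        raise GenotypeFormatError("first column of a genotype TSV must be 'individual_id'")
    if raw["individual_id"].duplicated().any():
        dup = raw.loc[raw["individual_id"].duplicated(), "individual_id"].iloc[0]
        raise DuplicateIdError(f"duplicate individual id {dup!r}")
    raw = raw.set_index("individual_id")
    parsed = {
        snp: [_parse_genotype_cell(v, ind, snp) for ind, v in col.items()]
        for snp, col in raw.items()
    }
    return GenotypeMatrix(pd.DataFrame(parsed, index=raw.index))


def write_genotypes_tsv(matrix: GenotypeMatrix, path) -> None:
    """Write the TSV dialect; integer dosages, missing as NA. Round-trip stable."""
    out = matrix.df.map(lambda v: "NA" if np.isnan(v) else str(int(v)))
    out.to_csv(path, sep="\t")


def read_genotypes_vcf(path, panel: Panel) -> GenotypeMatrix:
    """Read genotypes from a VCF, recoding to effect-allele counts.

    Only bi-allelic records whose id is in the panel are used.  The count is
    of the panel's effect allele whether it is REF or ALT; e.g. with effect
    allele == REF, a 1/1 call contributes zero effect alleles.
    """
    wanted = set(panel.snp_ids)
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        if len(set(samples)) != len(samples):
            raise DuplicateIdError("duplicate sample ids in VCF")
        columns: dict[str, list[float]] = {}
        for rec in vcf:
            if rec.id not in wanted:
                continue
            if rec.alts is None or len(rec.alts) != 1:
                raise GenotypeFormatError(f"{rec.id}: only bi-allelic records are supported")
            snp = panel[rec.id]
            ref, alt = rec.ref, rec.alts[0]
            if {ref, alt} != {snp.effect_allele, snp.other_allele}:
                raise AlleleMismatchError(
                    f"{rec.id}: VCF alleles {ref}/{alt} do not match panel "
                    f"{snp.effect_allele}/{snp.other_allele} (strand flips are not resolved)"
                )
            effect_index = 0 if ref == snp.effect_allele else 1
            col = []
            for sample in samples:
                alleles = rec.samples[sample]["GT"]
                if alleles is None or any(a is None for a in alleles):
                    col.append(math.nan)
                else:
                    col.append(float(sum(a == effect_index for a in alleles)))
            columns[rec.id] = col
    return GenotypeMatrix(pd.DataFrame(columns, index=pd.Index(samples, name="individual_id")))


def read_phenotypes(path) -> pd.DataFrame:
    """Read the phenotype/covariate table and append derived anthropometrics."""
    df = pd.read_csv(path, sep="\t", dtype={"individual_id": str})
    if "individual_id" not in df.columns:
        raise ValueError("phenotype table lacks an 'individual_id' column")
    return derive_anthropometrics(df.set_index("individual_id"))


def write_phenotypes(phenotypes: pd.DataFrame, path) -> None:
    phenotypes[PHENOTYPE_COLUMNS].to_csv(path, sep="\t")


def load_inputs(panel_path, genotype_path, phenotype_path, format_hint: str | None = None,
                weights_path=None):
    """Load and align the three inputs of an analysis run.

    Returns ``(panel, genotypes, phenotypes, report)`` where genotypes and
    phenotypes are restricted, in a stable order, to the individuals present
    in both tables, and ``report`` lists unmatched ids on either side.
    ``format_hint`` may be ``"tsv"`` or ``"vcf"``; by default the genotype
    format is inferred from the file extension.
    """
    panel = read_panel(panel_path, weights_path=weights_path)
    fmt = format_hint or ("vcf" if str(genotype_path).endswith((".vcf", ".vcf.gz")) else "tsv")
    if fmt == "vcf":
        genotypes = read_genotypes_vcf(genotype_path, panel)
    elif fmt == "tsv":
        genotypes = read_genotypes_tsv(genotype_path)
    else:
        raise ValueError(f"unknown genotype format {fmt!r}")

    overlap = [s for s in panel.snp_ids if s in set(genotypes.snp_ids)]
    if not overlap:
        raise ValueError("panel and genotype file share no SNPs")
    extra_snps = sorted(set(genotypes.snp_ids) - set(panel.snp_ids))
    genotypes = genotypes.subset_snps(overlap)

    phenotypes = read_phenotypes(phenotype_path)
    geno_ids = set(genotypes.individual_ids)
    pheno_ids = set(phenotypes.index)
    shared = [i for i in genotypes.individual_ids if i in pheno_ids]
    report = {
        "n_matched": len(shared),
        "genotype_only": sorted(geno_ids - pheno_ids),
        "phenotype_only": sorted(pheno_ids - geno_ids),
        "panel_snps_missing_from_genotypes": [s for s in panel.snp_ids if s not in set(overlap)],
        "genotype_snps_not_in_panel": extra_snps,
    }
    genotypes = genotypes.subset_individuals(shared)
    phenotypes = phenotypes.loc[shared]
    return panel, genotypes, phenotypes, report
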