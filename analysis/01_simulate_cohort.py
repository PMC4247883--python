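#!/usr/bin/env python
"""Generate the default synthetic cohort and write its input files.

Emulates the study conditions: 740 adults aged 30-64, genotyped on the
29-SNP BMI panel at the cohort's observed allele frequencies, 5% missing
calls, BMI driven by the weighted score (+0.15 kg/m² per risk allele) plus
covariates (~13.1% of variance) plus noise, obesity by thresholding BMI.

Writes panel/genotype/phenotype files under scratch/cohort/ (regenerable;
rerun this script before 02-06).
"""

import sys
from pathlib import Path

from gpscore import io as gio
from gpscore.synthetic_cohort import default_config, simulate_cohort

OUT = Path("scratch/cohort")
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1


def main() -> None:
    cfg = default_config(seed=SEED)
    cohort = simulate_cohort(cfg)
    OUT.mkdir(parents=True, exist_ok=True)
    gio.write_panel(cohort.panel, OUT / "panel.tsv")
    gio.write_genotypes_tsv(cohort.genotypes, OUT / "genotypes.tsv")
    cohort.phenotypes.to_csv(OUT / "phenotypes.tsv", sep="\t")
    (OUT / "seed.txt").write_text(f"{SEED}\n")
    n_miss = cohort.genotypes.df.isna().to_numpy().mean()
    print(f"simulated n={cfg.n} cohort (seed {SEED}) on {cohort.panel.size} SNPs")
    print(f"missing call fraction: {n_miss:.3f} (target {cfg.missing_rate})")
    print(f"obesity prevalence: {cohort.phenotypes['obese'].mean():.3f}")
    print(f"wrote {OUT}/panel.tsv, genotypes.tsv, phenotypes.tsv")


if __name__ == "__main__":
    main()
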