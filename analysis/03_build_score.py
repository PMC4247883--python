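#!/usr/bin/env python
"""Construct the weighted genetic predisposition score.

Mean-imputes missing genotypes, excludes individuals missing more than 3
SNPs, rescales the weighted sum to allele units (0-58 for 29 SNPs) and
assigns quartiles.  Writes results/scores.tsv.
"""

from pathlib import Path

from gpscore.gps_score import assign_quartiles, compute_scores
from gpscore.io import read_genotypes_tsv, read_panel

COHORT = Path("scratch/cohort")
OUT = Path("results")


def main() -> None:
    panel = read_panel(COHORT / "panel.tsv")
    genotypes = read_genotypes_tsv(COHORT / "genotypes.tsv")
    scores = compute_scores(genotypes, panel)
    kept = scores.loc[~scores["excluded"], "gps"]
    qa = assign_quartiles(kept)
    scores["quartile"] = qa.labels.reindex(scores.index)
    OUT.mkdir(exist_ok=True)
    scores.to_csv(OUT / "scores.tsv", sep="\t")
    print(f"scored {len(scores)} individuals; "
          f"{int(scores['excluded'].sum())} excluded (>3 missing genotypes)")
    print(f"score mean {kept.mean():.1f} +- {kept.std(ddof=1):.1f} alleles, "
          f"range {kept.min():.1f} to {kept.max():.1f}")
    print("quartile cut points: " + ", ".join(f"{c:.1f}" for c in qa.cut_points))
    print(f"wrote {OUT}/scores.tsv")


if __name__ == "__main__":
    main()
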