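# Methods

## Score model

The weighted genetic predisposition score assumes an additive genetic
model: each panel SNP contributes independently and linearly, with the
published per-allele effect `β_i` (kg/m² per effect allele) as its weight.
For coded genotypes `g_i ∈ {0,1,2}` the raw score `Σ β_i g_i` is bounded by
`2Σβ`; dividing by that bound and multiplying by the allele count `2m`
rescales it to allele units, so a score point is one average-weight risk
allele and the range is `[0, 2m]`. The rescaling is written generally
rather than with fixed constants so that any sub-panel renormalises
automatically: the bundled 29-SNP panel gives the familiar divide-by-8.24,
multiply-by-58 form, and the 25-SNP leave-out rerun maps onto 0–50 without
special-casing. The allele-unit score is invariant to multiplying all
weights by a positive constant, and reduces to the plain risk-allele count
when weights are equal (both tested).

Missing genotypes are mean-imputed: a missing cell takes the SNP's sample
mean allele count (`2 × EAF`), which preserves the cohort mean score and
avoids discarding individuals with sporadic failures. Imputation means are
computed on the full genotyped sample **before** the high-missingness
exclusion; the alternative order (means after exclusion) is available by
passing explicit means to `compute_scores`, and matters little at the
default 5% missingness. Individuals missing more than `max_missing = 3`
panel SNPs are flagged and excluded from analysis — at a 5% independent
missingness rate this removes ~6% of a cohort, matching the exclusion
fraction the emulated study reported.

### Panel weights

The panel file carries alleles and reference frequencies; the per-allele
weights of the original discovery GWAS are not redistributable here, so the
package bundles `synthetic_weights.tsv`: stand-in weights with a realistic
GWAS-like spread, constrained to sum to 4.12 kg/m² so the 29-SNP rescaling
constants (8.24, 58) are exact. They are clearly labelled synthetic; users
with the real weights supply them as a two-column TSV.

## SNP quality control

* **Genotype counts / EAF** over non-missing calls only; `EAF = (n1 +
  2n2)/2n`, identically half the mean coded genotype.
* **Hardy–Weinberg**: the default test is the Pearson 1-df goodness-of-fit
  χ² against expected proportions `((1−f)², 2f(1−f), f²)` at the sample
  EAF, no continuity correction. A monomorphic SNP returns `p = 1` (no
  measurable departure) instead of erroring, so small synthetic panels do
  not crash pipelines. An exact conditional test (sum of probabilities of
  heterozygote counts no more probable than observed, computed by the
  standard recurrence) is available via `exact=True`; it is more faithful
  for rare alleles, and some published panel p-values are reproduced better
  by one test than the other.
* **Call-rate filter**: SNPs with call rate below 95% are dropped; the
  threshold is inclusive (exactly 95% is kept). The scoring stage only ever
  sees SNPs that survived this filter.
* **Reference frequency comparison**: observed allele counts are tested
  (1-df goodness-of-fit) against fixed reference proportions, because
  reference sample counts are generally unavailable; this ignores sampling
  error in the reference and is therefore slightly anti-conservative for
  small reference studies.
* **Multiplicity**: QC flags use the Bonferroni threshold `α/m` with `m`
  the number of SNPs surviving the call-rate filter.

## Association models

Continuous traits use OLS, obesity uses maximum-likelihood logistic
regression; in both, inference on the exposure is Wald: 95% CI = estimate ±
1.96·SE and a two-sided p (t-based for OLS). Covariate encodings: sex as a
female indicator (male reference), physical activity as an ordinal 0–3
(none/low/medium/high), smoking as a current-smoker indicator by default
(never/former collapsed; a 3-level dummy coding is available — published
analyses rarely state which they used). Incomplete cases are deleted
listwise. Rank-deficient designs raise an error naming the collinear
columns; separation raises an explicit non-convergence error.

The quartile analysis recomputes cut points from the analysis sample
(quartile boundaries are sample statistics, not method constants), ties at
a cut point go to the upper quartile, and quartiles 2–4 enter an adjusted
logistic model as indicators against quartile 1. A quartile with no cases
or no controls has an undefined OR; its individuals are dropped from the
indicator fit so the remaining contrasts stay estimable, and its row is
reported as inestimable. The trend p comes from a separate model with the
quartile index as a single ordinal 0–3 term — the common epidemiological
convention. Obesity analyses must exclude overweight individuals
(25 ≤ BMI < 30): they are neither normal-weight controls nor obese cases;
the pipeline does this removal itself.

Explained variance is decomposed as `R²(trait ~ score)`,
`R²(trait ~ score + covariates)` on the same complete-case sample, and
their difference as the covariate increment.

Direction-consistency of per-SNP effects uses the exact one-sided binomial
tail `P(X ≥ k | n, ½)`; a beta of exactly zero counts as inconsistent
(documented tie rule). A normal approximation without continuity
correction is provided for comparison but the exact test is primary.

## Synthetic cohorts

The generator emulates a cross-sectional adult cohort: ages uniform on
[30, 64], 52% female (409/787), configurable smoking/activity categories,
and genotypes drawn independently per SNP as binomial(2, EAF) — in
Hardy–Weinberg proportions by construction — at the allele frequencies the
bundled panel observed in the emulated cohort. Calls are then masked
completely at random at 5%.

BMI follows an explicit variance budget:

```
BMI = 26.5 + 0.15·(GPS − E[GPS]) + c·Z + ε,   Var(BMI) = 5.5²
```

where `Z` is a centred, unit-variance combination of the four covariates
(standardised in closed form from their theoretical means/variances; signs:
age +, female −, activity −, current smoking +), `c²` is set to 13.1% of
the total variance, and `ε` receives the remainder. The genetic share is
then `0.15²·Var(GPS)/5.5² ≈ 0.94%` with the bundled panel
(`SD(GPS) ≈ 3.55`), so a crude sample R² lands near 1% once the ~`1/n`
finite-sample inflation is counted. The total SD of 5.5 kg/m² is a package
default chosen to make the triple {0.15 per allele, SD(GPS)≈3.6, crude
R²≈1%} internally consistent; it is configurable, and an infeasible budget
(components exceeding the total) raises immediately. The per-allele effect
acts on the score computed from *complete* genotypes; missingness is
applied afterwards to the observed matrix, so scoring-stage imputation is
exercised against a known truth. Height is drawn by sex and weight
back-derived so the Quetelet equation reproduces the simulated BMI
exactly; waist and hip are generated from BMI alone plus noise, making
their score associations mediated by BMI by construction (the mediation
the BMI-adjusted models should and do erase). BMI is floored at
13 kg/m² (~0.1% of draws) to keep anthropometry physical.

Obesity labels come in two modes. *Threshold* mode (default) classifies the
simulated BMI at the standard cutoffs, so labels and BMI are perfectly
consistent. *Logistic* mode sets `P(case) = expit(α + ln(OR)·(GPS − mean) +
γ·Z)` with per-allele OR 1.11 and the intercept solved numerically for a
33% target prevalence; it guarantees the target OR is the true parameter,
which is what the odds-ratio recovery analyses need. Every stage draws from
sub-seeds spawned deterministically from one integer seed; identical
configurations produce byte-identical cohorts.

### What the generator does not emulate

No linkage disequilibrium between SNPs, no Hardy–Weinberg departures, no
correlation between genotypes and covariates (so adjusted and crude genetic
effects coincide in expectation), missingness strictly at random, Gaussian
trait noise, and no measurement error in anthropometry. Passing recovery
tests therefore demonstrate correctness of the scoring and modelling
machinery under the stated assumptions — not robustness to confounding,
informative missingness or LD, which real cohorts can exhibit.

One deliberate consequence of masking calls at exactly the 5% rate: each
SNP's realised call rate is a binomial draw centred *on* the 95% QC bar, so
in any single simulated cohort roughly a third to a half of SNPs fall just
below it. The pipeline honours the bar (it never scores failed-QC SNPs);
the recovery and acceptance analyses score the full panel directly, as a
study whose per-SNP success rates were all ≥95% would.

## Numerical and design choices

* BMI classes are half-open exactly as defined: normal < 25,
  overweight [25, 30), obese ≥ 30; BMI is stored unrounded.
* VCF genotypes are re-oriented to effect-allele counts using the panel as
  the authority; strand flips are never guessed — an allele-pair mismatch
  is an error, because silent strand resolution corrupts scores for A/T and
  C/G SNPs.
* Missing-genotype spellings `NA`, `.`, `./.`, `.|.` and the empty cell all
  normalise to one internal missing value.
* Quartile assignment needs at least four distinct, spread-out values so
  the cut points are strictly increasing.
* Replicate sizes: the recovery analyses use 50 cohorts of n = 740 (the
  emulated analysis size), which puts the Monte-Carlo SE of the mean
  per-allele effect near 0.008 — comfortably inside the ±0.02 check band.
  CI-coverage checks use 1000 complete-data replicates, because a coverage
  proportion estimated from 50 replicates has an SE (~3%) wider than the
  ±2% band being checked.

## Known limitations

* The allele-frequency comparison treats the reference EAF as fixed.
* The exact HWE recurrence is O(rare-allele count) per SNP — fine for
  cohort panels, not tuned for biobank scale.
* Listwise deletion is the only missing-covariate strategy; no multiple
  imputation.
* Per-SNP association reuses a full OLS fit per SNP; for panels of tens of
  SNPs this is instant, but it is not vectorised for genome-wide use.
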