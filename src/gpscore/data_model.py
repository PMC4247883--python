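"""Domain types shared by every stage of the score pipeline.

The central objects are a :class:`Panel` of SNP definitions (effect allele,
other allele, per-allele weight in kg/m² from published GWAS estimates), a
:class:`GenotypeMatrix` of coded effect-allele counts (0/1/2, missing as NaN),
and a phenotype table with the anthropometric derivations (BMI via the
Quetelet equation, waist-to-hip ratio, BMI class).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VALID_ALLELES = frozenset("ACGT")

#: Accepted spellings of a missing genotype in input files.
MISSING_TOKENS = frozenset({"NA", ".", "./.", ".|.", ""})

BMI_OVERWEIGHT_CUT = 25.0
BMI_OBESE_CUT = 30.0


class GenotypeFormatError(ValueError):
    """A genotype file contains a value outside {0, 1, 2, missing}."""


class AlleleMismatchError(ValueError):
    """Panel alleles do not match the alleles observed in a genotype file."""


class DuplicateIdError(ValueError):
    """Duplicate individual or SNP identifiers in an input table."""


class ConfigurationError(ValueError):
    """An analysis or simulation configuration is internally inconsistent."""


class NonConvergenceError(RuntimeError):
    """A maximum-likelihood fit failed to converge (e.g. separation)."""


class SingularDesignError(ValueError):
    """The model design matrix is rank deficient."""


@dataclass(frozen=True)
class SnpDef:
    """One panel SNP: identity, allele coding and per-allele weight.

    Parameters
    ----------
    snp_id : str
        rs identifier.
    locus_label : str
        Nearby gene or locus name, for reporting only.
    effect_allele : str
        The allele whose copies are counted 0/1/2; its published effect on
        BMI is trait-raising by convention.
    other_allele : str
        The complementary allele; must differ from ``effect_allele``.
    weight : float
        Published per-allele effect size (kg/m² per effect allele), >= 0.
    reference_eaf : float, optional
        Effect-allele frequency in the reference (discovery) population.
    """

    snp_id: str
    locus_label: str
    effect_allele: str
    other_allele: str
    weight: float
    reference_eaf: float | None = None

    def __post_init__(self) -> None:
        if self.effect_allele not in VALID_ALLELES:
            raise ValueError(f"{self.snp_id}: invalid effect allele {self.effect_allele!r}")
        if self.other_allele not in VALID_ALLELES:
            raise ValueError(f"{self.snp_id}: invalid other allele {self.other_allele!r}")
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.snp_id}: effect and other allele are identical")
        if not np.isfinite(self.weight) or self.weight < 0:
            raise ValueError(f"{self.snp_id}: weight must be a non-negative real")
        if self.reference_eaf is not None and not 0.0 <= self.reference_eaf <= 1.0:
            raise ValueError(f"{self.snp_id}: reference EAF outside [0, 1]")


@dataclass(frozen=True)
class Panel:
    """An ordered SNP panel with unique identifiers and positive total weight."""

    snps: tuple[SnpDef, ...]
    name: str = "panel"

    def __post_init__(self) -> None:
        if len(self.snps) < 1:
            raise ValueError("panel must contain at least one SNP")
        ids = [s.snp_id for s in self.snps]
        if len(set(ids)) != len(ids):
            raise DuplicateIdError("panel contains duplicate SNP ids")
        if self.weight_sum <= 0:
            raise ValueError("panel weight sum must be positive")

    @property
    def snp_ids(self) -> list[str]:
        return [s.snp_id for s in self.snps]

    @property
    def size(self) -> int:
        return len(self.snps)

    @property
    def weight_sum(self) -> float:
        """Sum of per-allele weights; twice this is the maximum raw score."""
        return float(sum(s.weight for s in self.snps))

    @property
    def weights(self) -> pd.Series:
        return pd.Series({s.snp_id: s.weight for s in self.snps}, name="weight")

    def __getitem__(self, snp_id: str) -> SnpDef:
        for s in self.snps:
            if s.snp_id == snp_id:
                return s
        raise KeyError(snp_id)

    def __contains__(self, snp_id: str) -> bool:
        return any(s.snp_id == snp_id for s in self.snps)

    def subset(self, keep: list[str] | None = None, exclude: list[str] | None = None,
               name: str | None = None) -> "Panel":
        """Return a reduced panel, preserving order.

        ``keep`` and ``exclude`` are mutually exclusive; unknown ids in
        ``exclude`` raise so a sensitivity rerun cannot silently no-op.
        """
        if (keep is None) == (exclude is None):
            raise ValueError("provide exactly one of keep / exclude")
        if exclude is not None:
            unknown = set(exclude) - set(self.snp_ids)
            if unknown:
                raise KeyError(f"exclusion list not in panel: {sorted(unknown)}")
            kept = tuple(s for s in self.snps if s.snp_id not in set(exclude))
        else:
            keep_set = set(keep)  # type: ignore[arg-type]
            unknown = keep_set - set(self.snp_ids)
            if unknown:
                raise KeyError(f"keep list not in panel: {sorted(unknown)}")
            kept = tuple(s for s in self.snps if s.snp_id in keep_set)
        return Panel(kept, name=name or f"{self.name}_subset")


@dataclass
class GenotypeMatrix:
    """Individuals × SNPs matrix of effect-allele counts.

    Values are floats: 0.0, 1.0, 2.0, or NaN for a missing call. Rows are
    indexed by individual id, columns by SNP id; both must be unique.
    """

    df: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if self.df.index.has_duplicates:
            raise DuplicateIdError("duplicate individual ids in genotype matrix")
        if self.df.columns.has_duplicates:
            raise DuplicateIdError("duplicate SNP ids in genotype matrix")
        values = self.df.to_numpy(dtype=float)
        bad = ~(np.isnan(values) | np.isin(values, (0.0, 1.0, 2.0)))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise GenotypeFormatError(
                f"invalid genotype {values[i, j]!r} for individual "
                f"{self.df.index[i]!r} at SNP {self.df.columns[j]!r}"
            )
        self.df = self.df.astype(float)
        self.df.index.name = "individual_id"

    @property
    def individual_ids(self) -> list[str]:
        return list(self.df.index)

    @property
    def snp_ids(self) -> list[str]:
        return list(self.df.columns)

    @property
    def n_individuals(self) -> int:
        return self.df.shape[0]

    def column(self, snp_id: str) -> pd.Series:
        if snp_id not in self.df.columns:
            raise KeyError(f"unknown SNP id {snp_id!r}")
        return self.df[snp_id]

    def call_rate(self) -> pd.Series:
        """Per-SNP fraction of non-missing calls."""
        return self.df.notna().mean(axis=0).rename("call_rate")

    def n_missing_per_individual(self) -> pd.Series:
        return self.df.isna().sum(axis=1).rename("n_missing")

    def subset_snps(self, snp_ids: list[str]) -> "GenotypeMatrix":
        missing = set(snp_ids) - set(self.df.columns)
        if missing:
            raise KeyError(f"SNPs not in matrix: {sorted(missing)}")
        return GenotypeMatrix(self.df[list(snp_ids)].copy())

    def subset_individuals(self, ids: list[str]) -> "GenotypeMatrix":
        return GenotypeMatrix(self.df.loc[list(ids)].copy())


def compute_bmi(weight_kg, height_m):
    """Body-mass index by the Quetelet equation, weight / height².

    Accepts scalars or arrays; both arguments must be strictly positive.
    """
    w = np.asarray(weight_kg, dtype=float)
    h = np.asarray(height_m, dtype=float)
    if np.any(w <= 0) or np.any(h <= 0):
        raise ValueError("weight and height must be strictly positive")
    out = w / h**2
    return float(out) if out.ndim == 0 else out


def classify_bmi(bmi):
    """BMI class with half-open boundaries: normal <25, overweight [25,30), obese >=30."""
    b = np.asarray(bmi, dtype=float)
    if np.any(~np.isfinite(b)) or np.any(b <= 0):
        raise ValueError("BMI must be positive and finite")
    classes = np.where(b < BMI_OVERWEIGHT_CUT, "normal",
                       np.where(b < BMI_OBESE_CUT, "overweight", "obese"))
    return str(classes) if classes.ndim == 0 else classes


PHENOTYPE_COLUMNS = ["age", "sex", "smoking", "activity", "weight", "height", "waist", "hip"]
SEX_LEVELS = ("male", "female")
SMOKING_LEVELS = ("never", "current", "former")
ACTIVITY_LEVELS = ("none", "low", "medium", "high")


def derive_anthropometrics(phenotypes: pd.DataFrame) -> pd.DataFrame:
    """Validate a phenotype table and append bmi, whr and bmi_class columns.

    The input must be indexed by individual id and carry
    ``age, sex, smoking, activity, weight (kg), height (m), waist (cm), hip (cm)``.
    """
    df = phenotypes.copy()
    missing = [c for c in PHENOTYPE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"phenotype table lacks columns: {missing}")
    if df.index.has_duplicates:
        raise DuplicateIdError("duplicate individual ids in phenotype table")
    for col, levels in (("sex", SEX_LEVELS), ("smoking", SMOKING_LEVELS),
                        ("activity", ACTIVITY_LEVELS)):
        bad = set(df[col].dropna()) - set(levels)
        if bad:
            raise ValueError(f"unknown {col} levels: {sorted(bad)}")
    for col in ("weight", "height", "waist", "hip"):
        if (df[col] <= 0).any():
            raise ValueError(f"non-positive values in {col}")
    df["bmi"] = compute_bmi(df["weight"], df["height"])
    df["whr"] = df["waist"] / df["hip"]
    df["bmi_class"] = classify_bmi(df["bmi"])
    df.index.name = "individual_id"
    return df
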