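"""Cohort tables: loading, validation, phenotype/exposure coding, HWE checks.

The analysis operates on a per-subject table holding seven candidate-SNP
genotypes (3-level categorical codes), a recent-negative-life-event (RLE)
count, lifetime depression (DEP, binary), Brief Symptom Inventory weighted
depression/anxiety scores (BSI-DEP, BSI-ANX, each in [0, 4]), plus age, sex
and a population/site descriptor.  This module houses the coding rules that
turn raw measurements into the categorical variables the Bayesian-network
and GLM arms consume, and the cohort-level summaries (genotype counts,
Hardy-Weinberg equilibrium tests, Table-1 style description).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

ROLES = frozenset({"genotype", "exposure", "phenotype", "covariate", "descriptor"})
KINDS = frozenset({"categorical", "count", "continuous", "binary"})

BSI_CATEGORIES = ("low", "moderate", "severe")
RLE_CATEGORIES = ("low", "moderate", "high")

#: The seven candidate polymorphisms, in the order the cohort table lists them.
SNP_NAMES = (
    "5-HTTLPR",
    "rs6265",
    "rs6295",
    "rs6311",
    "rs7766029",
    "rs7958311",
    "rs8836",
)

#: Gene symbol per polymorphism (for reporting only).
SNP_GENES = {
    "5-HTTLPR": "SLC6A4",
    "rs6265": "BDNF",
    "rs6295": "HTR1A",
    "rs6311": "HTR2A",
    "rs7766029": "CB1",
    "rs7958311": "P2RX7",
    "rs8836": "GALR2",
}

#: Genotype level labels, ordered (major homozygote, heterozygote, minor homozygote).
SNP_LEVELS = {
    "5-HTTLPR": ("ll", "sl", "ss"),
    "rs6265": ("GG", "AG", "AA"),
    "rs6295": ("GG", "GC", "CC"),
    "rs6311": ("CC", "CT", "TT"),
    "rs7766029": ("CC", "CT", "TT"),
    "rs7958311": ("GG", "AG", "AA"),
    "rs8836": ("CC", "CG", "GG"),
}

#: Published whole-cohort genotype counts (major hom, het, minor hom), n = 1682.
#: These printed counts are inputs: they seed the HWE checks, the summary
#: fixtures and the default allele frequencies of the synthetic generator.
COHORT_GENOTYPE_COUNTS = {
    "5-HTTLPR": (556, 819, 307),
    "rs6265": (1128, 484, 70),
    "rs6295": (425, 845, 412),
    "rs6311": (569, 832, 281),
    "rs7766029": (443, 868, 371),
    "rs7958311": (983, 610, 89),
    "rs8836": (580, 820, 282),
}

#: Published cohort description (whole-cohort counts, n = 1682).
COHORT_DESCRIPTION = {
    "n_total": 1682,
    "sex": {"male": 509, "female": 1173},
    "dep": {"no": 958, "yes": 724},
    "rle_category": {"low": 1134, "moderate": 311, "high": 237},
    "bsi_dep_category": {"low": 1133, "moderate": 290, "severe": 259},
    "bsi_anx_category": {"low": 1096, "moderate": 339, "severe": 247},
    "age_mean": 33.23,
    "age_sd": 10.53,
}


@dataclass(frozen=True)
class VariableSpec:
    """Declaration of one analysis variable: its role and admissible values."""

    name: str
    role: str
    kind: str
    levels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r} for variable {self.name!r}")
        if self.kind not in KINDS:
            raise ValueError(f"unknown kind {self.kind!r} for variable {self.name!r}")
        if self.kind == "categorical" and not self.levels:
            raise ValueError(f"categorical variable {self.name!r} needs levels")


def default_dictionary() -> list[VariableSpec]:
    """Variable roster of the depression cohort analysis.

    Seven SNP genotypes, the RLE exposure count, three phenotype components
    (DEP, BSI-DEP, BSI-ANX), age and sex as covariates, and the recruitment
    site as a population descriptor.
    """
    specs = [
        VariableSpec("id", "descriptor", "categorical", ("*",)),
        VariableSpec("age", "covariate", "continuous"),
        VariableSpec("sex", "covariate", "categorical", ("male", "female")),
        VariableSpec("population", "descriptor", "categorical", ("BUD", "MAN")),
    ]
    specs += [
        VariableSpec(snp, "genotype", "categorical", SNP_LEVELS[snp]) for snp in SNP_NAMES
    ]
    specs += [
        VariableSpec("rle_count", "exposure", "count"),
        VariableSpec("dep", "phenotype", "binary"),
        VariableSpec("bsi_dep", "phenotype", "continuous"),
        VariableSpec("bsi_anx", "phenotype", "continuous"),
    ]
    return specs


@dataclass
class CohortTable:
    """Validated per-subject table plus its data dictionary.

    ``frame`` holds one row per subject with columns named after the
    dictionary entries.  Only complete cases survive validation: rows with a
    missing value or a value outside its declared domain are dropped (and
    counted), never imputed.
    """

    frame: pd.DataFrame
    dictionary: list[VariableSpec] = field(default_factory=default_dictionary)
    n_rejected: int = 0

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def snp_names(self) -> list[str]:
        return [v.name for v in self.dictionary if v.role == "genotype"]

    def spec(self, name: str) -> VariableSpec:
        for v in self.dictionary:
            if v.name == name:
                return v
        raise KeyError(name)

    def rle_category(self) -> pd.Series:
        """Per-subject RLE exposure category (low/moderate/high)."""
        return self.frame["rle_count"].map(categorize_rle)

    def bsi_category(self, which: str) -> pd.Series:
        """Categorized BSI score; ``which`` is 'bsi_dep' or 'bsi_anx'."""
        return self.frame[which].map(categorize_bsi)

    def genotype_counts(self, snp: str) -> "GenotypeCounts":
        levels = self.spec(snp).levels
        counts = self.frame[snp].value_counts()
        return GenotypeCounts(
            snp,
            int(counts.get(levels[0], 0)),
            int(counts.get(levels[1], 0)),
            int(counts.get(levels[2], 0)),
        )


@dataclass(frozen=True)
class GenotypeCounts:
    """Observed genotype counts for one SNP: (major hom, het, minor hom)."""

    snp: str
    n_hom_major: int
    n_het: int
    n_hom_minor: int

    @property
    def total(self) -> int:
        return self.n_hom_major + self.n_het + self.n_hom_minor

    @property
    def minor_allele_frequency(self) -> float:
        """Allele-counting estimate (2·minor hom + het) / 2N."""
        if self.total == 0:
            raise ValueError("no genotyped subjects")
        return (2 * self.n_hom_minor + self.n_het) / (2 * self.total)


def score_bsi(item_scores: Sequence[object], missing=None) -> float:
    """Weighted BSI score: sum of completed items / number completed.

    Items are 0-4 integer responses; ``missing`` (None, NaN or a sentinel)
    marks a skipped item.  At least one completed item is required.
    """
    completed = [
        float(x)
        for x in item_scores
        if x is not missing and x is not None and not (isinstance(x, float) and math.isnan(x))
    ]
    if not completed:
        raise ValueError("all BSI items missing")
    if any(x < 0 or x > 4 for x in completed):
        raise ValueError("BSI item responses must lie in [0, 4]")
    return sum(completed) / len(completed)


def categorize_bsi(score: float) -> str:
    """Categorize a weighted BSI score: low [0,1), moderate [1,2), severe [2,4]."""
    if not 0.0 <= score <= 4.0:
        raise ValueError(f"BSI score {score} outside [0, 4]")
    if score < 1.0:
        return "low"
    if score < 2.0:
        return "moderate"
    return "severe"


def categorize_rle(count: int) -> str:
    """Categorize an RLE count: low 0-1, moderate 2, high 3 or more."""
    if count < 0:
        raise ValueError(f"negative RLE count {count}")
    if count <= 1:
        return "low"
    if count == 2:
        return "moderate"
    return "high"


def hwe_test(counts: GenotypeCounts, exact: bool = False) -> tuple[float, float]:
    """Hardy-Weinberg equilibrium test for one SNP's genotype counts.

    The canonical test is the 1-df chi-square goodness of fit of observed
    (hom-major, het, hom-minor) counts against the expected proportions
    (p^2, 2pq, q^2) at the allele-counting frequency estimate.  With
    ``exact=True`` the mid-p-free exact test of Wigginton-Cutler-Abecasis
    is computed instead (the chi-square remains the reference variant).

    Returns ``(chi_square, p_value)``; for the exact variant chi_square is
    reported as NaN.
    """
    n = counts.total
    if n == 0:
        raise ValueError("zero genotyped subjects")
    q = counts.minor_allele_frequency
    p = 1.0 - q
    if q == 0.0 or q == 1.0:
        logger.warning("monomorphic SNP %s: HWE test degenerate, p = 1", counts.snp)
        return 0.0, 1.0
    if exact:
        return math.nan, _hwe_exact_p(counts.n_het, counts.n_hom_minor, counts.n_hom_major)
    expected = np.array([n * p * p, 2 * n * p * q, n * q * q])
    observed = np.array([counts.n_hom_major, counts.n_het, counts.n_hom_minor], dtype=float)
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    p_value = float(stats.chi2.sf(chi2, df=1))
    return chi2, p_value


def _hwe_exact_p(n_het: int, n_hom_minor: int, n_hom_major: int) -> float:
    """Exact HWE p-value: sum of heterozygote-count probabilities <= observed's."""
    n = n_het + n_hom_minor + n_hom_major
    n_minor = 2 * n_hom_minor + n_het
    n_minor = min(n_minor, 2 * n - n_minor)
    hets = range(n_minor % 2, n_minor + 1, 2)
    logprobs = []
    for h in hets:
        hom_min = (n_minor - h) // 2
        hom_maj = n - h - hom_min
        lp = (
            h * math.log(2)
            + math.lgamma(n + 1)
            - math.lgamma(h + 1)
            - math.lgamma(hom_min + 1)
            - math.lgamma(hom_maj + 1)
            + math.lgamma(n_minor + 1)
            + math.lgamma(2 * n - n_minor + 1)
            - math.lgamma(2 * n + 1)
        )
        logprobs.append(lp)
    probs = np.exp(np.array(logprobs) - max(logprobs))
    probs /= probs.sum()
    observed_idx = list(hets).index(min(n_het, n_minor))
    return float(probs[probs <= probs[observed_idx] + 1e-12].sum())


def _round_half_up(x: float, ndigits: int = 1) -> float:
    factor = 10**ndigits
    return math.floor(x * factor + 0.5) / factor


def percentage(count: int, total: int) -> float:
    """Percent of total, rounded half-up to one decimal (table presentation)."""
    if total == 0:
        raise ValueError("empty total")
    return _round_half_up(100.0 * count / total, 1)


def summarize_cohort(cohort: CohortTable) -> pd.DataFrame:
    """Cohort description: counts and percentages per category, overall and per site.

    Mirrors a population-description table: sex, lifetime depression, RLE
    exposure category, BSI depression/anxiety categories and the genotype
    distribution of every SNP, each with counts and 1-decimal percentages
    for the whole cohort and per population label.
    """
    df = cohort.frame
    blocks: list[tuple[str, pd.Series]] = [
        ("sex", df["sex"]),
        ("dep", df["dep"].map({0: "no", 1: "yes"})),
        ("rle_category", cohort.rle_category()),
        ("bsi_dep_category", cohort.bsi_category("bsi_dep")),
        ("bsi_anx_category", cohort.bsi_category("bsi_anx")),
    ]
    blocks += [(snp, df[snp]) for snp in cohort.snp_names]

    level_order = {
        "sex": ("male", "female"),
        "dep": ("no", "yes"),
        "rle_category": RLE_CATEGORIES,
        "bsi_dep_category": BSI_CATEGORIES,
        "bsi_anx_category": BSI_CATEGORIES,
        **{snp: cohort.spec(snp).levels for snp in cohort.snp_names},
    }

    populations = sorted(df["population"].unique()) if "population" in df else []
    rows = []
    for var, series in blocks:
        for level in level_order[var]:
            row = {"variable": var, "level": level}
            count = int((series == level).sum())
            row["count"] = count
            row["percent"] = percentage(count, len(df))
            for pop in populations:
                mask = df["population"] == pop
                sub = int((series[mask] == level).sum())
                row[f"count_{pop}"] = sub
                row[f"percent_{pop}"] = percentage(sub, int(mask.sum())) if mask.any() else math.nan
            rows.append(row)
    return pd.DataFrame(rows)


def hwe_table(cohort: CohortTable | None = None, exact: bool = False) -> pd.DataFrame:
    """HWE chi-square and p-value per SNP.

    Without a cohort, the published whole-cohort genotype counts are used.
    """
    rows = []
    for snp in SNP_NAMES if cohort is None else cohort.snp_names:
        if cohort is None:
            maj, het, minor = COHORT_GENOTYPE_COUNTS[snp]
            gc = GenotypeCounts(snp, maj, het, minor)
        else:
            gc = cohort.genotype_counts(snp)
        chi2, p = hwe_test(gc, exact=exact)
        rows.append(
            {
                "snp": snp,
                "gene": SNP_GENES.get(snp, ""),
                "n": gc.total,
                "maf": gc.minor_allele_frequency,
                "chi_square": chi2,
                "p_value": p,
            }
        )
    return pd.DataFrame(rows)


def _validate_row(row: pd.Series, dictionary: Iterable[VariableSpec]) -> str | None:
    """Return a rejection reason, or None if the row is a valid complete case."""
    for spec in dictionary:
        if spec.name not in row.index:
            continue
        value = row[spec.name]
        if pd.isna(value):
            return f"missing {spec.name}"
        if spec.kind == "categorical" and spec.levels != ("*",):
            if str(value) not in spec.levels:
                return f"{spec.name}={value!r} not in {spec.levels}"
        elif spec.kind == "count":
            if float(value) < 0 or float(value) != int(float(value)):
                return f"{spec.name}={value!r} not a non-negative integer"
        elif spec.kind == "binary":
            if int(value) not in (0, 1):
                return f"{spec.name}={value!r} not binary"
        elif spec.name in ("bsi_dep", "bsi_anx"):
            if not 0.0 <= float(value) <= 4.0:
                return f"{spec.name}={value} outside [0, 4]"
        elif spec.name == "age":
            if float(value) <= 0:
                return f"age={value} not positive"
    return None


def from_dataframe(
    df: pd.DataFrame, dictionary: list[VariableSpec] | None = None
) -> CohortTable:
    """Validate a raw dataframe into a complete-case CohortTable."""
    dictionary = dictionary or default_dictionary()
    names = [v.name for v in dictionary if v.name in df.columns]
    missing_cols = [
        v.name for v in dictionary if v.name not in df.columns and v.name != "id"
    ]
    if missing_cols:
        raise ValueError(f"columns missing from input: {missing_cols}")
    reasons = df.apply(_validate_row, axis=1, dictionary=dictionary)
    bad = reasons.notna()
    if bad.any():
        for idx, reason in reasons[bad].items():
            logger.info("rejecting row %s: %s", idx, reason)
        logger.warning("rejected %d of %d rows as incomplete/invalid", bad.sum(), len(df))
    kept = df.loc[~bad, names].reset_index(drop=True).copy()
    if len(kept) == 0:
        raise ValueError("zero valid rows after validation")
    for col in ("dep",):
        kept[col] = kept[col].astype(int)
    kept["rle_count"] = kept["rle_count"].astype(int)
    for col in ("age", "bsi_dep", "bsi_anx"):
        kept[col] = kept[col].astype(float)
    return CohortTable(kept, dictionary, n_rejected=int(bad.sum()))


def read_cohort(
    path,
    dictionary: list[VariableSpec] | None = None,
    sep: str | None = None,
    na_values: str | Sequence[str] = "NA",
) -> CohortTable:
    """Read a delimited cohort table (TSV/CSV, header row) and validate it.

    The delimiter is sniffed from the extension unless given; missing values
    are encoded by ``na_values`` (default ``"NA"``).  Invalid rows are
    logged and dropped; an empty or header-mismatched file raises.
    """
    dictionary = dictionary or default_dictionary()
    if sep is None:
        sep = "," if str(path).endswith(".csv") else "\t"
    try:
        df = pd.read_csv(path, sep=sep, na_values=na_values, dtype={"id": str})
    except pd.errors.EmptyDataError as err:
        raise ValueError(f"empty cohort file: {path}") from err
    if df.empty:
        raise ValueError(f"cohort file has no data rows: {path}")
    return from_dataframe(df, dictionary)


def write_cohort(cohort: CohortTable, path, sep: str = "\t") -> None:
    """Write the cohort table as delimited text."""
    cohort.frame.to_csv(path, sep=sep, index=False)
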