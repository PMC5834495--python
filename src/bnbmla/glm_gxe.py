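"""Frequentist gene x environment confirmation: nested GLM ladder.

Fits the nested sequence of ordinary-least-squares models on a composite
depression phenotype —

    null:    age + sex
    Model-1: null + RLE exposure
    Model-2: Model-1 + genetic main effects
    Model-3: Model-2 + SNP x RLE interactions

— and compares them by residual-variance F-tests:

    F = [(SSE_small - SSE_big) / (df_small - df_big)] / [SSE_big / df_big]

with the p-value from the F distribution.  Genotypes enter the linear
models as 2-df categorical factors (no dominance assumption); RLE enters
as a 2-df categorical factor or, for the sensitivity analysis, as the raw
event count (1 df).  A per-SNP logistic regression of lifetime depression
with additive genotype coding checks for genetic main effects.

The composite phenotype is the mean of the three standardized components
(DEP as 0/1, the BSI depression/anxiety categories as 0/1/2); per-component
univariate ladders are available for sensitivity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort_data import BSI_CATEGORIES, CohortTable, RLE_CATEGORIES

logger = logging.getLogger(__name__)

TERM_BLOCKS = ("covariates", "rle_main", "genetic_main", "gxe_interactions")


@dataclass(frozen=True)
class GlmModelSpec:
    """Which term blocks a model contains and how RLE is coded."""

    response: str = "composite"  # composite | dep | bsi_dep | bsi_anx
    terms: tuple[str, ...] = ("covariates",)
    rle_coding: str = "categorical"  # categorical (2 df) | continuous (1 df)

    def __post_init__(self) -> None:
        unknown = set(self.terms) - set(TERM_BLOCKS)
        if unknown:
            raise ValueError(f"unknown term blocks: {sorted(unknown)}")
        if "covariates" not in self.terms:
            raise ValueError("age and sex covariates are always present")
        if self.rle_coding not in ("categorical", "continuous"):
            raise ValueError("rle_coding must be 'categorical' or 'continuous'")

    def is_nested_in(self, other: "GlmModelSpec") -> bool:
        return (
            set(self.terms) < set(other.terms)
            and self.response == other.response
            and self.rle_coding == other.rle_coding
        )


@dataclass
class FittedGlm:
    """OLS fit summary: coefficients, residual sum of squares, df, R^2."""

    spec: GlmModelSpec
    coef: np.ndarray
    column_names: list[str]
    sse: float
    df_resid: int
    r_squared: float
    n_cases: int
    rank: int
    n_dropped_columns: int = 0


@dataclass
class ModelComparison:
    """Nested-model contrast: F statistic, degrees of freedom, p, R^2 change."""

    f_stat: float
    df_num: int
    df_den: int
    p_value: float
    r2_small: float
    r2_big: float

    @property
    def delta_r2(self) -> float:
        return self.r2_big - self.r2_small


def build_composite_phenotype(cohort: CohortTable) -> np.ndarray:
    """Composite depression score: mean of standardized phenotype components.

    Components are DEP (0/1) and the BSI depression/anxiety categories coded
    0/1/2.  Each is z-scored before averaging; a zero-variance component is
    left unstandardized (centered only) with a warning.
    """
    parts = {
        "dep": cohort.frame["dep"].to_numpy(dtype=float),
        "bsi_dep": cohort.bsi_category("bsi_dep").map(
            {c: i for i, c in enumerate(BSI_CATEGORIES)}
        ).to_numpy(dtype=float),
        "bsi_anx": cohort.bsi_category("bsi_anx").map(
            {c: i for i, c in enumerate(BSI_CATEGORIES)}
        ).to_numpy(dtype=float),
    }
    cols = []
    for name, values in parts.items():
        sd = values.std()
        if sd == 0:
            logger.warning("phenotype component %s has zero variance; centered only", name)
            cols.append(values - values.mean())
        else:
            cols.append((values - values.mean()) / sd)
    return np.mean(cols, axis=0)


def _response_vector(cohort: CohortTable, response: str) -> np.ndarray:
    if response == "composite":
        return build_composite_phenotype(cohort)
    if response == "dep":
        return cohort.frame["dep"].to_numpy(dtype=float)
    if response in ("bsi_dep", "bsi_anx"):
        return (
            cohort.bsi_category(response)
            .map({c: i for i, c in enumerate(BSI_CATEGORIES)})
            .to_numpy(dtype=float)
        )
    raise ValueError(f"unknown response {response!r}")


def _dummies(series: pd.Series, levels: Sequence[str], prefix: str) -> tuple[np.ndarray, list[str]]:
    """Treatment-coded indicator columns for all non-reference levels."""
    cols, names = [], []
    for level in levels[1:]:
        cols.append((series == level).to_numpy(dtype=float))
        names.append(f"{prefix}[{level}]")
    return np.column_stack(cols) if cols else np.empty((len(series), 0)), names


def build_design_matrix(
    cohort: CohortTable, spec: GlmModelSpec
) -> tuple[np.ndarray, list[str]]:
    """Assemble the design matrix for a model spec (intercept included)."""
    df = cohort.frame
    n = len(df)
    blocks: list[np.ndarray] = [np.ones((n, 1))]
    names: list[str] = ["intercept"]

    age = df["age"].to_numpy(dtype=float)
    blocks.append(((age - age.mean()) / (age.std() or 1.0)).reshape(-1, 1))
    names.append("age")
    sex_cols, sex_names = _dummies(df["sex"], cohort.spec("sex").levels, "sex")
    blocks.append(sex_cols)
    names.extend(sex_names)

    if spec.rle_coding == "categorical":
        rle_cols, rle_names = _dummies(cohort.rle_category(), RLE_CATEGORIES, "rle")
    else:
        rle_cols = df["rle_count"].to_numpy(dtype=float).reshape(-1, 1)
        rle_names = ["rle_count"]

    if "rle_main" in spec.terms:
        blocks.append(rle_cols)
        names.extend(rle_names)

    snp_cols: list[np.ndarray] = []
    snp_names: list[str] = []
    for snp in cohort.snp_names:
        c, cn = _dummies(df[snp], cohort.spec(snp).levels, snp)
        snp_cols.append(c)
        snp_names.extend(cn)
    if "genetic_main" in spec.terms:
        blocks.extend(snp_cols)
        names.extend(snp_names)

    if "gxe_interactions" in spec.terms:
        all_snp = np.column_stack(snp_cols) if snp_cols else np.empty((n, 0))
        for j in range(rle_cols.shape[1]):
            blocks.append(all_snp * rle_cols[:, j : j + 1])
            names.extend(f"{sn}:{rle_names[j]}" for sn in snp_names)

    return np.column_stack(blocks), names


def fit_glm(cohort: CohortTable, spec: GlmModelSpec) -> FittedGlm:
    """Ordinary-least-squares fit of a model spec on the chosen response.

    Rank-deficient designs are handled by the least-norm solution; the
    residual degrees of freedom use the numerical rank, and the number of
    aliased columns is reported.
    """
    y = _response_vector(cohort, spec.response)
    X, names = build_design_matrix(cohort, spec)
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ coef
    sse = float(((y - fitted) ** 2).sum())
    sst = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - sse / sst if sst > 0 else 0.0
    n_dropped = X.shape[1] - rank
    if n_dropped:
        logger.info("design matrix rank-deficient: %d aliased column(s)", n_dropped)
    return FittedGlm(
        spec=spec,
        coef=coef,
        column_names=names,
        sse=sse,
        df_resid=len(y) - rank,
        r_squared=r2,
        n_cases=len(y),
        rank=rank,
        n_dropped_columns=n_dropped,
    )


def compare_nested(small: FittedGlm, big: FittedGlm) -> ModelComparison:
    """Residual-variance F-test of a nested model pair."""
    if small.n_cases != big.n_cases:
        raise ValueError("models fitted on different case sets")
    if not small.spec.is_nested_in(big.spec):
        raise ValueError("small model's terms must be a strict subset of big's")
    df_num = small.df_resid - big.df_resid
    if df_num <= 0:
        raise ValueError("big model adds no estimable parameters")
    df_den = big.df_resid
    f_stat = max(0.0, (small.sse - big.sse) / df_num) / (big.sse / df_den)
    p_value = float(stats.f.sf(f_stat, df_num, df_den))
    return ModelComparison(
        f_stat=float(f_stat),
        df_num=int(df_num),
        df_den=int(df_den),
        p_value=p_value,
        r2_small=small.r_squared,
        r2_big=big.r_squared,
    )


@dataclass
class ModelLadder:
    """Results of the Model-1/2/3 nested comparison on one cohort."""

    m1_vs_null: ModelComparison
    m2_vs_m1: ModelComparison
    m3_vs_m1: ModelComparison
    m3_vs_m2: ModelComparison
    variance_table: pd.DataFrame
    rle_coding: str
    response: str

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for label, cmp_ in (
            ("Model-1 vs null", self.m1_vs_null),
            ("Model-2 vs Model-1", self.m2_vs_m1),
            ("Model-3 vs Model-1", self.m3_vs_m1),
            ("Model-3 vs Model-2", self.m3_vs_m2),
        ):
            rows.append(
                {
                    "comparison": label,
                    "df1": cmp_.df_num,
                    "df2": cmp_.df_den,
                    "F": cmp_.f_stat,
                    "p_value": cmp_.p_value,
                    "r2_small": cmp_.r2_small,
                    "r2_big": cmp_.r2_big,
                    "delta_r2": cmp_.delta_r2,
                }
            )
        return pd.DataFrame(rows)


def run_model_ladder(
    cohort: CohortTable, rle_coding: str = "categorical", response: str = "composite"
) -> ModelLadder:
    """Fit the null / Model-1 / Model-2 / Model-3 ladder and all contrasts.

    The variance table reports, per model, the total R^2 and the R^2
    attributable to each term block beyond the age+sex covariates
    (R^2(covariates + block) - R^2(covariates)) — both readings of
    "variance explained" are thereby available.
    """
    specs = {
        "null": GlmModelSpec(response, ("covariates",), rle_coding),
        "m1": GlmModelSpec(response, ("covariates", "rle_main"), rle_coding),
        "m2": GlmModelSpec(response, ("covariates", "rle_main", "genetic_main"), rle_coding),
        "m3": GlmModelSpec(
            response,
            ("covariates", "rle_main", "genetic_main", "gxe_interactions"),
            rle_coding,
        ),
    }
    fits = {k: fit_glm(cohort, s) for k, s in specs.items()}
    genetic_only = fit_glm(
        cohort, GlmModelSpec(response, ("covariates", "genetic_main"), rle_coding)
    )
    r2_cov = fits["null"].r_squared
    variance_table = pd.DataFrame(
        [
            {"model": "null (age+sex)", "r2_total": r2_cov, "r2_beyond_covariates": 0.0},
            {
                "model": "Model-1 (RLE)",
                "r2_total": fits["m1"].r_squared,
                "r2_beyond_covariates": fits["m1"].r_squared - r2_cov,
            },
            {
                "model": "genetic mains only",
                "r2_total": genetic_only.r_squared,
                "r2_beyond_covariates": genetic_only.r_squared - r2_cov,
            },
            {
                "model": "Model-2 (RLE + genetic mains)",
                "r2_total": fits["m2"].r_squared,
                "r2_beyond_covariates": fits["m2"].r_squared - r2_cov,
            },
            {
                "model": "Model-3 (+ GxE interactions)",
                "r2_total": fits["m3"].r_squared,
                "r2_beyond_covariates": fits["m3"].r_squared - r2_cov,
            },
        ]
    )
    return ModelLadder(
        m1_vs_null=compare_nested(fits["null"], fits["m1"]),
        m2_vs_m1=compare_nested(fits["m1"], fits["m2"]),
        m3_vs_m1=compare_nested(fits["m1"], fits["m3"]),
        m3_vs_m2=compare_nested(fits["m2"], fits["m3"]),
        variance_table=variance_table,
        rle_coding=rle_coding,
        response=response,
    )


def compare_nested_multivariate(
    cohort: CohortTable, small: GlmModelSpec, big: GlmModelSpec
) -> ModelComparison:
    """Pillai-trace contrast of nested models on the three-component response.

    Sensitivity alternative to the composite score: the three standardized
    phenotype components form a multivariate response; the hypothesis
    cross-product matrix of the added term block is tested with Pillai's
    trace and its standard F approximation.
    """
    if not small.is_nested_in(big):
        raise ValueError("small model's terms must be a strict subset of big's")
    comps = ["dep", "bsi_dep", "bsi_anx"]
    Y = np.column_stack([_response_vector(cohort, c) for c in comps])
    Y = (Y - Y.mean(axis=0)) / np.where(Y.std(axis=0) == 0, 1.0, Y.std(axis=0))
    Xs, _ = build_design_matrix(cohort, small)
    Xb, _ = build_design_matrix(cohort, big)

    def resid(X):
        beta, _, rank, _ = np.linalg.lstsq(X, Y, rcond=None)
        return Y - X @ beta, rank

    Rs, _ = resid(Xs)
    Rb, rank_b = resid(Xb)
    E = Rb.T @ Rb
    H = Rs.T @ Rs - E
    eigvals = np.real(np.linalg.eigvals(np.linalg.solve(H + E, H)))
    pillai = float(np.clip(eigvals, 0, 1).sum())
    p = Y.shape[1]
    rank_s = np.linalg.matrix_rank(Xs)
    q = rank_b - rank_s  # hypothesis df
    n = Y.shape[0]
    s = min(p, q)
    m = (abs(p - q) - 1) / 2
    nn = (n - rank_b - p - 1) / 2
    df1 = int(s * (2 * m + s + 1))
    df2 = int(s * (2 * nn + s + 1))
    f_stat = (pillai / (s - pillai)) * (df2 / df1) if s > pillai else np.inf
    return ModelComparison(
        f_stat=float(f_stat),
        df_num=df1,
        df_den=df2,
        p_value=float(stats.f.sf(f_stat, df1, df2)),
        r2_small=0.0,
        r2_big=pillai / s,  # average canonical explained fraction
    )


@dataclass
class LogisticEffect:
    """Per-SNP additive logistic regression result for lifetime depression."""

    snp: str
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    flagged: bool = False  # separation / non-convergence


def logistic_main_effects(cohort: CohortTable) -> list[LogisticEffect]:
    """Logistic check for genetic main effects on lifetime depression.

    One fit per SNP: DEP ~ age + sex + population + genotype (additive
    0/1/2 minor-allele count).  Returns the genotype odds ratio with 95%
    Wald interval and p-value.  Fits hit by separation or non-convergence
    are refit with an L2 penalty and flagged.
    """
    import statsmodels.api as sm

    df = cohort.frame
    base = pd.DataFrame(
        {
            "age": (df["age"] - df["age"].mean()) / (df["age"].std() or 1.0),
            "sex": (df["sex"] == cohort.spec("sex").levels[1]).astype(float),
        }
    )
    pop_levels = cohort.spec("population").levels
    for level in pop_levels[1:]:
        base[f"pop[{level}]"] = (df["population"] == level).astype(float)
    y = df["dep"].to_numpy(dtype=float)

    results = []
    for snp in cohort.snp_names:
        levels = cohort.spec(snp).levels
        additive = df[snp].map({levels[0]: 0, levels[1]: 1, levels[2]: 2}).astype(float)
        X = sm.add_constant(base.assign(genotype=additive), has_constant="add")
        flagged = False
        try:
            with np.errstate(all="ignore"):
                fit = sm.Logit(y, X).fit(disp=False, maxiter=100)
            if not fit.mle_retvals.get("converged", True):
                raise RuntimeError("no convergence")
            beta = fit.params["genotype"]
            se = fit.bse["genotype"]
            p = float(fit.pvalues["genotype"])
        except Exception:  # separation or failed convergence: penalized refit
            flagged = True
            logger.warning("logistic fit for %s flagged; using L2-penalized refit", snp)
            with np.errstate(all="ignore"):
                fit = sm.Logit(y, X).fit_regularized(alpha=1.0, L1_wt=0.0, disp=False)
            beta = fit.params["genotype"]
            se = np.nan
            p = np.nan
        half = 1.959963984540054 * se
        results.append(
            LogisticEffect(
                snp=snp,
                odds_ratio=float(np.exp(beta)),
                ci_low=float(np.exp(beta - half)) if np.isfinite(half) else np.nan,
                ci_high=float(np.exp(beta + half)) if np.isfinite(half) else np.nan,
                p_value=p,
                flagged=flagged,
            )
        )
    return results
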