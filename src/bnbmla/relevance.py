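"""Stress-stratified Bayesian relevance analysis.

Orchestrates the headline analysis: within each RLE exposure stratum
(low / moderate / high), a structure-MCMC run over the discretized analysis
variables estimates, for every candidate SNP, the posterior probability of
membership in the Markov blanket of the joint phenotype target set
{DEP, BSI-DEP, BSI-ANX} — the "strong relevance" posterior — together with
a pairwise interaction score measuring joint Markov-blanket occurrence of
SNP pairs.  Posteriors above 0.5 are conventionally read as strong
relevance and below 0.1 as non-relevance.

The interaction score is reported in two simple readings: the joint
membership posterior itself, and its lift (joint divided by the product of
the marginals), so either normalization can be inspected.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bn_core import DiscreteDataset
from .cohort_data import (
    BSI_CATEGORIES,
    CohortTable,
    RLE_CATEGORIES,
)
from .structure_mcmc import (
    ConvergenceReport,
    McmcConfig,
    McmcRun,
    convergence_report,
    mbm_posterior,
    run_structure_mcmc,
)

logger = logging.getLogger(__name__)

TARGET_VARIABLES = ("dep", "bsi_dep_category", "bsi_anx_category")
DEFAULT_MIN_STRATUM = 50


@dataclass(frozen=True)
class RelevanceThresholds:
    """Posterior cutoffs for relevance classification."""

    strong: float = 0.5
    non_relevant: float = 0.1

    def __post_init__(self) -> None:
        if not 0.0 <= self.non_relevant < self.strong <= 1.0:
            raise ValueError("need 0 <= non_relevant < strong <= 1")


@dataclass
class PairScore:
    """Interaction score record for one unordered variable pair."""

    pair: frozenset
    joint: float
    product: float
    lift: float


@dataclass
class RelevanceResult:
    """Per-stratum relevance posteriors and pairwise interaction scores."""

    stratum: str
    n_subjects: int
    posteriors: dict[str, float]
    interaction: list[PairScore]
    run: McmcRun
    diagnostics: ConvergenceReport
    age_bin_edges: np.ndarray | None = None

    def classified(self, thresholds: RelevanceThresholds | None = None) -> dict[str, str]:
        thresholds = thresholds or RelevanceThresholds()
        return {
            name: classify_relevance(pr, thresholds) for name, pr in self.posteriors.items()
        }

    def to_frame(self, thresholds: RelevanceThresholds | None = None) -> pd.DataFrame:
        cls = self.classified(thresholds)
        return pd.DataFrame(
            {
                "stratum": self.stratum,
                "variable": list(self.posteriors),
                "posterior": list(self.posteriors.values()),
                "class": [cls[v] for v in self.posteriors],
                "n_subjects": self.n_subjects,
            }
        )


def classify_relevance(pr: float, thresholds: RelevanceThresholds | None = None) -> str:
    """Map a relevance posterior to {non_relevant, intermediate, strong}."""
    if not 0.0 <= pr <= 1.0:
        raise ValueError(f"posterior {pr} outside [0, 1]")
    thresholds = thresholds or RelevanceThresholds()
    if pr < thresholds.non_relevant:
        return "non_relevant"
    if pr > thresholds.strong:
        return "strong"
    return "intermediate"


def discretize_covariates(
    cohort: CohortTable,
    n_age_bins: int = 3,
    include_population: bool = False,
    include_rle: bool = False,
) -> tuple[DiscreteDataset, dict]:
    """Build the discrete analysis dataset for the Bayesian-network arm.

    Age is cut at empirical quantiles into ``n_age_bins`` ordinal bins
    (tertiles by default); sex, genotypes and the categorized phenotype
    components pass through as categoricals.  The bin edges are returned in
    the mapping record for reporting.  RLE and the population descriptor
    are excluded unless requested (RLE defines the strata; population is
    added only for the stratification check).
    """
    df = cohort.frame
    if df["age"].nunique() < n_age_bins:
        raise ValueError(
            f"only {df['age'].nunique()} distinct ages; cannot form {n_age_bins} bins"
        )
    age_binned, edges = pd.qcut(
        df["age"], q=n_age_bins, labels=False, retbins=True, duplicates="drop"
    )
    if age_binned.nunique() < 2:
        raise ValueError("age discretization collapsed to a single bin")

    out = pd.DataFrame(
        {
            "age_bin": age_binned.astype(int).astype(str),
            "sex": df["sex"],
        }
    )
    levels: dict[str, tuple] = {
        "age_bin": tuple(str(b) for b in sorted(age_binned.unique())),
        "sex": cohort.spec("sex").levels,
    }
    for snp in cohort.snp_names:
        out[snp] = df[snp]
        levels[snp] = cohort.spec(snp).levels
    if include_rle:
        out["rle_category"] = cohort.rle_category()
        levels["rle_category"] = RLE_CATEGORIES
    if include_population:
        out["population"] = df["population"]
        levels["population"] = cohort.spec("population").levels
    out["dep"] = df["dep"].map({0: "no", 1: "yes"})
    levels["dep"] = ("no", "yes")
    out["bsi_dep_category"] = cohort.bsi_category("bsi_dep")
    out["bsi_anx_category"] = cohort.bsi_category("bsi_anx")
    levels["bsi_dep_category"] = BSI_CATEGORIES
    levels["bsi_anx_category"] = BSI_CATEGORIES

    # Drop declared levels absent from the data (cardinality must stay >= 2,
    # and empty categories carry no information for the discrete scores).
    pruned = {}
    for col in out.columns:
        observed = set(out[col].unique())
        pruned[col] = tuple(l for l in levels[col] if l in observed)
        if len(pruned[col]) < 2:
            raise ValueError(f"variable {col!r} is constant within this subset")
    mapping = {"age_bin_edges": edges, "levels": pruned}
    return DiscreteDataset.from_dataframe(out, pruned), mapping


def interaction_scores(
    run: McmcRun, variables: list[str] | None = None
) -> list[PairScore]:
    """Joint Markov-blanket co-membership scores for all unordered pairs.

    For each pair: ``joint`` is the posterior that both variables are in the
    target Markov blanket simultaneously, ``product`` the product of their
    marginal posteriors, and ``lift`` their ratio (0 when the product is 0).
    Joint <= min(marginals) always holds for sample frequencies.
    """
    if run.n_recorded == 0:
        raise ValueError("no recorded samples: interaction scores undefined")
    variables = variables or [n for n in run.names if n not in run.targets]
    scores = []
    for a, b in itertools.combinations(variables, 2):
        i, j = run.names.index(a), run.names.index(b)
        joint = run.pair_counts[i, j] / run.n_recorded
        pa = run.mbm_counts[i] / run.n_recorded
        pb = run.mbm_counts[j] / run.n_recorded
        product = pa * pb
        lift = joint / product if product > 0 else 0.0
        scores.append(PairScore(frozenset((a, b)), float(joint), float(product), float(lift)))
    return scores


def _relevance_for_subset(
    cohort: CohortTable,
    label: str,
    config: McmcConfig,
    n_age_bins: int,
    include_population: bool,
) -> RelevanceResult:
    dataset, mapping = discretize_covariates(
        cohort, n_age_bins=n_age_bins, include_population=include_population
    )
    targets = [t for t in TARGET_VARIABLES if t in dataset.names]
    run = run_structure_mcmc(dataset, targets, config)
    candidates = [n for n in dataset.names if n not in targets]
    posteriors = {name: mbm_posterior(run, name) for name in candidates}
    snps = [s for s in cohort.snp_names if s in dataset.names]
    return RelevanceResult(
        stratum=label,
        n_subjects=len(cohort),
        posteriors=posteriors,
        interaction=interaction_scores(run, snps),
        run=run,
        diagnostics=convergence_report(run),
        age_bin_edges=mapping["age_bin_edges"],
    )


def stratified_relevance(
    cohort: CohortTable,
    config: McmcConfig,
    n_age_bins: int = 3,
    min_stratum: int = DEFAULT_MIN_STRATUM,
    include_population: bool = False,
) -> list[RelevanceResult]:
    """Run the relevance analysis separately within each RLE exposure stratum.

    Each stratum's subjects form their own MCMC problem; strata smaller than
    ``min_stratum`` are flagged and skipped.  Per-stratum seeds are split
    deterministically from ``config.seed`` so strata are reproducible
    independently.
    """
    results = []
    rle = cohort.rle_category()
    children = np.random.SeedSequence(config.seed).spawn(len(RLE_CATEGORIES))
    for stratum, seedseq in zip(RLE_CATEGORIES, children):
        mask = (rle == stratum).values
        n = int(mask.sum())
        if n < min_stratum:
            logger.warning(
                "stratum %s has %d subjects (< %d): skipped", stratum, n, min_stratum
            )
            continue
        sub = CohortTable(
            cohort.frame.loc[mask].reset_index(drop=True), cohort.dictionary
        )
        stratum_config = McmcConfig(
            burn_in=config.burn_in,
            n_steps=config.n_steps,
            max_parents=config.max_parents,
            seed=int(seedseq.generate_state(1)[0] % (2**31)),
            thinning=config.thinning,
            n_chains=config.n_chains,
            prior=config.prior,
            ess=config.ess,
        )
        results.append(
            _relevance_for_subset(sub, stratum, stratum_config, n_age_bins, include_population)
        )
    if not results:
        raise ValueError("no stratum met the minimum size")
    return results


def relevance_table(results: list[RelevanceResult], snps_only: bool = True) -> pd.DataFrame:
    """Long-format table of per-stratum posteriors (SNPs only by default)."""
    frames = [r.to_frame() for r in results]
    table = pd.concat(frames, ignore_index=True)
    if snps_only:
        keep = {"5-HTTLPR"} | {v for v in table["variable"] if v.startswith("rs")}
        table = table[table["variable"].isin(keep)].reset_index(drop=True)
    return table


@dataclass
class StratificationCheck:
    """Population-descriptor sensitivity: descriptor posterior and SNP shifts."""

    analysis: str  # "whole" or a stratum label
    descriptor_posterior: float
    snp_posterior_shift: dict[str, float]  # with-descriptor minus without

    @property
    def max_abs_shift(self) -> float:
        return max((abs(v) for v in self.snp_posterior_shift.values()), default=0.0)


def stratification_check(
    cohort: CohortTable,
    config: McmcConfig,
    n_age_bins: int = 3,
    min_stratum: int = DEFAULT_MIN_STRATUM,
    per_stratum: bool = True,
) -> list[StratificationCheck]:
    """Assess population-stratification bias.

    Reruns the relevance analysis with the population descriptor included as
    a candidate predictor — on the whole cohort and (optionally) within each
    RLE stratum — and reports the descriptor's own Markov-blanket posterior
    plus the signed shift of every SNP posterior relative to the run without
    the descriptor.
    """
    if cohort.frame["population"].nunique() < 2:
        raise ValueError("population descriptor has a single level")
    checks = []

    def compare(sub: CohortTable, label: str, cfg: McmcConfig) -> StratificationCheck:
        without = _relevance_for_subset(sub, label, cfg, n_age_bins, include_population=False)
        with_pop = _relevance_for_subset(sub, label, cfg, n_age_bins, include_population=True)
        shifts = {
            snp: with_pop.posteriors[snp] - without.posteriors[snp]
            for snp in sub.snp_names
            if snp in with_pop.posteriors and snp in without.posteriors
        }
        return StratificationCheck(label, with_pop.posteriors["population"], shifts)

    checks.append(compare(cohort, "whole", config))
    if per_stratum:
        rle = cohort.rle_category()
        children = np.random.SeedSequence(config.seed).spawn(len(RLE_CATEGORIES))
        for stratum, seedseq in zip(RLE_CATEGORIES, children):
            mask = (rle == stratum).values
            if int(mask.sum()) < min_stratum:
                continue
            sub = CohortTable(
                cohort.frame.loc[mask].reset_index(drop=True), cohort.dictionary
            )
            cfg = McmcConfig(
                burn_in=config.burn_in,
                n_steps=config.n_steps,
                max_parents=config.max_parents,
                seed=int(seedseq.generate_state(1)[0] % (2**31)),
                thinning=config.thinning,
                n_chains=config.n_chains,
                prior=config.prior,
                ess=config.ess,
            )
            checks.append(compare(sub, stratum, cfg))
    return checks
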