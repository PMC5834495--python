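# Methods

## The statistical model

The package treats relevance of a predictor for a multivariate outcome as a
structural property of discrete Bayesian networks.  For variables
X₁,…,X_p with cardinalities rᵢ and complete cases, the marginal likelihood
of a DAG G factorizes over nodes; each local factor, under a uniform
Dirichlet(1,…,1) prior on the conditional distributions (the
Cooper–Herskovits / K2 metric), is

P(Dᵢ | Paᵢ(G)) = ∏ⱼ [(rᵢ−1)! / (Nᵢⱼ+rᵢ−1)!] ∏ₖ Nᵢⱼₖ! ,

where j indexes observed parent configurations, Nᵢⱼₖ counts cases with
node i in state k under configuration j, and Nᵢⱼ = Σₖ Nᵢⱼₖ.  All factors
are evaluated in log space via log-gamma; unobserved parent configurations
contribute log 1 = 0.  With a uniform prior over DAGs (subject to an
in-degree bound of 5), the unnormalized log posterior of a structure is the
sum of local log scores, so Metropolis–Hastings ratios reduce to local
score differences.

Relevance of a variable V for the target set T = {DEP, BSI-DEP, BSI-ANX}
is Markov-blanket membership: V ∈ MB(T) iff V is a parent, child, or
co-parent of a child of some target.  The **strong-relevance posterior**
is P(V ∈ MB(T) | D), estimated by the frequency of the property among
sampled structures (Bayesian model averaging).  The pairwise interaction
score for SNPs U, V reports both the joint posterior
P(U ∈ MB(T) ∧ V ∈ MB(T) | D) and its lift (joint / product of marginals),
because "joint occurrence in relevant models" admits either normalization;
joint ≤ min(marginals) holds by construction.

A BDeu prior with configurable equivalent sample size is available
(`prior="bdeu"`, `ess=`) for sensitivity analysis; Cooper–Herskovits is
canonical throughout.

## The sampler

Structure MCMC uses single-edge moves — add, delete, reverse — drawn
uniformly from the valid neighborhood of the current DAG (moves violating
acyclicity or the parent bound are excluded *before* sampling), with the
Hastings correction log |N(G)| − log |N(G′)|.  Neighborhoods are computed
with boolean matrix algebra: reachability by repeated squaring, a length-≥2
path test (A·R) for reversal legality.  Chains start from the empty DAG;
per-chain seeds are spawned deterministically from the master seed; local
scores are memoized in a cache shared across chains (cached values are
exact, so sharing couples no randomness).  Default 3 chains pooled by
count-weighted averaging; `convergence_report` flags a between-chain
posterior range above 0.05.

Two profiles: *desk* (default; tens of thousands of steps, minutes on one
CPU) and *paper-faithful* (10⁶ burn-in + 5×10⁶ steps per run).  On
3–4-variable problems the sampler matches exhaustive enumeration to
sup-norm ≈ 0.006–0.008 at 10⁵ recorded states — the package's central
correctness check, run routinely in the test suite.  At the full 12-variable
problem the posterior is multimodal and desk-scale chains can disagree
(spreads up to ~0.9 in small strata); the diagnostics expose this honestly,
pooling averages over modes, and the paper-faithful profile is the remedy
when accuracy at the third decimal matters.

### Small-sample behavior of the relevance posterior

A uniform prior over DAGs places substantial mass on structures containing
any given variable in MB(T) (≈ 0.69 at 4 nodes).  Data shrink irrelevant
variables toward 0, but the rate depends on n: at n ≈ 1100 null SNP
posteriors sit near 0.01–0.05, while at n ≈ 240–315 (the moderate/high
exposure strata) the *exact* null posterior for a 3-level variable is
typically 0.1–0.5 — verified by full enumeration on 5-variable problems,
where the sampler reproduces the exact values.  Consequences: (i) near-zero
posteriors are only attainable in large strata, so null-specificity checks
are formulated on the large low-exposure stratum; (ii) small-stratum
posteriors must be read against this elevated null floor, and a "strong"
call at n ≈ 250 carries prior mass as well as evidence.  This is a property
of the scoring model, not of the implementation.

## Phenotype and exposure coding

BSI weighted scores are the mean of completed 0–4 item responses
(missing items excluded; at least one required), categorized low [0,1),
moderate [1,2), severe [2,4].  RLE counts are categorized low 0–1,
moderate 2, high ≥3; analyses run separately per stratum.  Age enters the
network arm as empirical tertiles (configurable bin count, edges logged);
sex and genotypes pass through as categoricals.  Hardy–Weinberg equilibrium
is checked per SNP with a 1-df chi-square against (p², 2pq, q²) at the
allele-counting frequency estimate, without continuity correction; an exact
test is available behind a flag.  Validation is complete-case: rows with
missing or out-of-domain values are logged and dropped, never imputed.

## The GLM arm

The composite phenotype is the mean of the three standardized component
codes (DEP as 0/1, BSI categories as 0/1/2); per-component responses and a
Pillai-trace multivariate contrast are available for sensitivity.  Designs
use treatment-coded factors: genotypes 2-df, RLE 2-df categorical or 1-df
continuous (raw count), interactions as factor products; age is
standardized, fits are ordinary least squares with rank-deficiency handled
by the least-norm solution (aliased columns counted and reported).  Nested
models are compared by

F = [(SSE_small − SSE_big)/(df_small − df_big)] / [SSE_big/df_big],

and "variance explained" is reported both as total R² and as R²
attributable beyond the age+sex covariates, since either reading is
defensible.  Significance threshold 0.05, no multiple-testing correction in
this arm (the Bayesian arm handles multiplicity through the posterior over
structures).  The logistic main-effects check fits one additive-coded
(0/1/2) logistic regression per SNP with age, sex and site as covariates;
separation or non-convergence triggers a flagged L2-penalized refit.

## The synthetic-cohort generator

Per subject: age ~ Normal(33.2, 10.5²) truncated at 18; sex Bernoulli
(0.70 female); site Bernoulli (0.60); genotypes g_j ∈ {0,1,2} at
Hardy–Weinberg proportions with allele frequencies computed from the
study's published genotype counts; stress category s ∈ {0,1,2} drawn
directly at the published proportions (0.674, 0.185, 0.141), with a
count-mode alternative (Poisson, λ = 1.1, categorized by the standard rule)
for the continuous-RLE sensitivity analysis.  The latent liability is

L = β₀ + β_age·age′ + β_sex·female + β_RLE·s + Σⱼ β_g[j]·g_j
    + Σⱼ γ[j]·g_j·s + β_site·site + ε,  ε ~ N(0, 1),

and the three phenotype components are DEP = 1{L + η₀ > 0} and monotone
piecewise-linear maps of L + η₁, L + η₂ onto the [0,4] BSI scale whose
category boundaries fall at the liability cutpoints (η ~ N(0, 0.5²)
independent).  The shared L induces the strong positive inter-correlation
of the components (rank correlations ≈ 0.6–0.75); the jitters keep them
distinct.

Defaults are the study conditions: genetic main effects zero; two variants
(rs6265, rs8836 — the analysis's top-ranked genes) carry an interaction
coefficient γ = 0.15 each.  The remaining free scalars were calibrated
once, jointly, against the study's printed margins and then frozen:
β_RLE = 0.21 so the stress main effect explains ≈ 6% of composite-phenotype
variance beyond covariates (the printed Model-1 share); β₀ = −0.54 and
cutpoints (0.32, 0.99) so the simulated DEP rate is ≈ 0.43 and the BSI
category proportions ≈ 67/17/15; γ chosen so the nested-GLM contrasts land
in the study's qualitative regime — interaction contrast clearly
significant (median p ≈ 0.005), main-effects contrast hovering at the
boundary (median p ≈ 0.1), matching the printed (0.0016, 0.086) pattern.
Age/sex coefficients (0.1, 0.2) are small nuisance effects of plausible
sign.

Because the interaction enters uncentered (γ·g·s with s ∈ {0,1,2}), it
*induces* a marginal genetic main effect of size γ·E[s]; the Model-2 and
Model-3 contrasts therefore trade off along a single power curve, and at
the study's sample size the attainable operating point is
P(interaction detected) ≈ 0.8 with P(mains not detected) ≈ 0.7 — the
generator reproduces the study's pattern in expectation but individual
20-cohort panels fluctuate around those rates.  What the generator does
*not* emulate: linkage disequilibrium between variants, gene–environment
correlation, differential-susceptibility (positive-environment) effects,
population-substructure confounding beyond an optional site effect on
liability, and item-level BSI responses.  Passing recovery tests therefore
demonstrate sensitivity to interaction-only architectures under clean
ascertainment, not robustness to those real-data complications.

## Numerical and design choices

- All probability arithmetic in log space; factorials via `gammaln`;
  normalization via log-sum-exp; exact enumeration guarded at 5 nodes
  (29 281 labeled DAGs).
- Exhaustive DAG enumeration iterates parent-set bitmasks per node and
  filters by a topological-sort acyclicity check; counts are validated
  against the known labeled-DAG sequence (3, 25, 543, …).
- Move proposals never generate invalid states, so acceptance compares only
  score and neighborhood sizes; the identity move covers the (practically
  unreachable) deadlocked case.
- Strata smaller than 50 subjects are skipped with a warning; a constant
  variable within a stratum raises rather than silently dropping.
- Percentages in summary tables are rounded half-up to one decimal to match
  the conventional presentation; a 3-level variable can therefore sum to
  100.1.
- Master seeds fan out via `numpy.random.SeedSequence.spawn` to stages,
  strata and chains, so any stratum is recomputable in isolation and full
  pipeline runs are byte-identical under a fixed seed.

## Known limitations

- Desk-scale chains under-mix on the 12-variable problem; treat desk-scale
  posteriors as screening values and use the paper-faithful profile (or
  more chains) for reportable numbers.
- The exact-enumeration oracle stops at 5 variables; above that, correctness
  rests on the small-instance checks plus counter invariants.
- The GLM arm's composite response is one defensible reduction of a
  three-component phenotype; conclusions sensitive to the reduction should
  be checked against the per-component and Pillai-trace variants.
- Real cohort tables must arrive as categorical genotype codes; no
  VCF/PLINK ingestion.
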