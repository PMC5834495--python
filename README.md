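# bnbmla — stress-stratified Bayesian relevance analysis of candidate gene variants

Candidate-gene studies of depression are notoriously hard to replicate.  One
proposed reason is that risk variants act mainly through gene × environment
(G×E) interaction: their effects surface only in people exposed to stress, so
analyses that ignore exposure dilute them away.  `bnbmla` implements, as a
reusable and tested pipeline, the analysis strategy behind that claim:

1. **Bayesian relevance analysis (BN-BMLA).**  Within each stratum of recent
   negative life-event (RLE) exposure — low (0–1 events), moderate (2),
   high (≥3) — a Metropolis–Hastings random walk over directed acyclic graphs
   samples Bayesian-network structures for the analysis variables (seven SNP
   genotypes, age, sex, and the three-component depression phenotype).
   Structures are scored with the Cooper–Herskovits (K2) marginal likelihood
   under a uniform structure prior,

   P(Dᵢ | Paᵢ) = ∏ⱼ [(rᵢ−1)! / (Nᵢⱼ+rᵢ−1)!] ∏ₖ Nᵢⱼₖ!,

   and each variant's **strong-relevance posterior** is the sampled frequency
   with which it belongs to the Markov blanket of the joint phenotype target
   set {DEP, BSI-DEP, BSI-ANX} (pr > 0.5 ≈ strong relevance, pr < 0.1 ≈
   non-relevance).  A pairwise **interaction score** — the posterior of joint
   Markov-blanket membership, with its lift normalization — measures
   gene–gene co-occurrence in relevant models.

2. **Nested-GLM confirmation.**  On a composite phenotype (mean of the
   standardized DEP, BSI-DEP, BSI-ANX codes), nested ordinary-least-squares
   models — Model-1: covariates + RLE; Model-2: + genetic main effects
   (2-df factors); Model-3: + SNP×RLE interactions — are compared by
   residual-variance F-tests.  An interaction-only genetic architecture
   yields a significant Model-3 contrast with a non-significant Model-2
   contrast.  A per-SNP additive logistic regression checks for main effects
   on lifetime depression, and Hardy–Weinberg chi-square tests validate the
   genotype distributions.

3. **Synthetic cohorts.**  A generator draws HWE genotypes at the study's
   allele frequencies, categorical stress exposure at its category
   proportions, and the three correlated phenotype components from a shared
   latent liability in which genetic effects enter **only** through
   gene × stress interaction — the architecture the analysis is designed to
   detect — enabling parameter-recovery and calibration studies.

The package is aimed at biostatisticians and psychiatric-genetics
researchers who want to apply or scrutinize stratified Bayesian relevance
analysis on candidate-SNP cohorts.

## Worked example

```python
from bnbmla import (McmcConfig, gxe_config, simulate_cohort,
                    stratified_relevance, run_model_ladder)

sim = simulate_cohort(gxe_config(n_subjects=1700, seed=7))   # rs6265 & rs8836 causal
results = stratified_relevance(sim.cohort,
                               McmcConfig(burn_in=5000, n_steps=25_000,
                                          n_chains=2, seed=11))
for r in results:
    print(r.stratum, {s: round(r.posteriors[s], 2) for s in ("rs6265", "rs8836")})
ladder = run_model_ladder(sim.cohort)
print(f"M2 vs M1: F={ladder.m2_vs_m1.f_stat:.2f} p={ladder.m2_vs_m1.p_value:.3f}")
print(f"M3 vs M1: F={ladder.m3_vs_m1.f_stat:.2f} p={ladder.m3_vs_m1.p_value:.4f}")
```

prints (seeds as above):

```
low {'rs6265': 0.03, 'rs8836': 0.09}
moderate {'rs6265': 0.09, 'rs8836': 0.27}
high {'rs6265': 0.94, 'rs8836': 0.98}
M2 vs M1: F=1.52 p=0.095
M3 vs M1: F=1.90 p=0.0005
```

The two truly interacting variants are non-relevant in the unexposed
stratum and strongly relevant under exposure, and the GLM ladder shows the
same decomposition: no detectable genetic main effects (Model-2), a
significant gene × stress interaction block (Model-3).  The scripts in
`examples/` walk through each capability (simulation, HWE checks,
sampler-vs-enumeration validation, stratified relevance, the GLM ladder,
and the full pipeline); the `bnbmla` console command exposes the same steps
as thin subcommands (`simulate`, `summarize`, `hwe`, `relevance`, `glm`,
`run`).

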