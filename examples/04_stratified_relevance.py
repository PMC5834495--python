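"""The headline analysis: per-stratum relevance posteriors for all SNPs.

Within each stress-exposure stratum, a structure MCMC estimates each
variant's posterior probability of belonging to the Markov blanket of the
joint phenotype {DEP, BSI-DEP, BSI-ANX}.  On an interaction-only synthetic
cohort the causal variants surface in the exposed strata and stay
non-relevant in the unexposed stratum.
"""

from bnbmla import McmcConfig, classify_relevance, gxe_config, simulate_cohort, stratified_relevance
from bnbmla.synthetic_cohort import DEFAULT_CAUSAL_SNPS

sim = simulate_cohort(gxe_config(n_subjects=1700, seed=2))
config = McmcConfig(burn_in=5_000, n_steps=25_000, n_chains=2, seed=11)
results = stratified_relevance(sim.cohort, config)

print(f"truly interacting variants: {', '.join(DEFAULT_CAUSAL_SNPS)}\n")
for r in results:
    print(f"stratum {r.stratum} (n={r.n_subjects}):")
    for snp in sim.cohort.snp_names:
        pr = r.posteriors[snp]
        mark = " <-- causal" if snp in DEFAULT_CAUSAL_SNPS else ""
        print(f"  {snp:<10} pr={pr:5.3f}  {classify_relevance(pr):<13}{mark}")
    print(f"  {r.diagnostics}")
    print()
print("Posteriors above 0.5 indicate strong relevance, below 0.1 non-relevance.")
print("The causal variants' posteriors rise with exposure while remaining in")
print("the non-relevant band for unexposed subjects — gene effects manifest")
print("only under stress.")
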