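"""Partitioned SNP-heritability by 3-component AI-REML.

The simulated trait carries h2 = 2% / 10% / 15% in the coding / buffer /
rest partitions (exact in-sample rescaling, so the truth is known; the
signal is stronger than the consumption-trait default so a small example
is informative).  One GRM per partition enters the REML fit alongside
sex, age, age^2 and site covariates; each component is then tested by a
boundary likelihood-ratio test against the model with that GRM dropped.
"""

from partherit import (
    SimConfig, VarianceComponentModel, build_partition, covariate_design,
    fit_greml, lrt_component, partitioned_greml, simulate_cohort,
)

cfg = SimConfig(n_samples=1200, n_snps=2400, h2_coding=0.02, h2_buffer=0.10,
                h2_rest=0.15, seed=3)
cohort = simulate_cohort(cfg)
assignment = build_partition(cohort.genes, cohort.panel, cfg.buffer_kb_truth)

fit, labels, grms = partitioned_greml(
    cohort.panel, assignment, cohort.phenotype, cohort.covariates
)
truth = {"coding": cfg.h2_coding, "buffer": cfg.h2_buffer, "rest": cfg.h2_rest}
print(f"converged in {fit.n_iter} iterations, logL = {fit.loglik:.2f}")
for k, lab in enumerate(labels):
    print(f"  h2_{lab:<6} = {fit.h2[k]:6.3f} (SE {fit.h2_se[k]:.3f})   "
          f"truth {truth[lab]:.3f}")
print(f"  residual  = {fit.h2[-1]:6.3f}")

# drop the buffer component and test it
X = covariate_design(cohort.covariates)
reduced_grms = [g for g, lab in zip(grms, labels) if lab != "buffer"]
reduced = fit_greml(VarianceComponentModel(reduced_grms, X, cohort.phenotype))
lrt, p = lrt_component(fit, reduced)
print(f"LRT for the buffer component: {lrt:.2f}, boundary p = {p:.4f}")
print("Estimates should cover the generating truths within ~2 SE; a small "
      "p confirms the buffer regions carry real signal.")
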