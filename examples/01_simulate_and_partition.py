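"""Simulate a cohort, run marker QC, and partition SNPs around the gene set.

Builds a small block-LD cohort, applies the standard marker filters
(per-sample call rate, MAF, HWE, missingness), and assigns every SNP to
coding / buffer / rest for a 10 kb flanking window.
"""

from partherit import QcThresholds, SimConfig, build_partition, qc_filter, simulate_cohort

cohort = simulate_cohort(SimConfig(n_samples=400, n_snps=1500, seed=7))
panel, report = qc_filter(cohort.panel, QcThresholds())
print(f"QC: kept {report['snps_kept']} SNPs / {report['samples_kept']} samples "
      f"(removed maf={report['maf_removed']}, hwe={report['hwe_removed']}, "
      f"missing={report['missing_removed']})")

assignment = build_partition(cohort.genes, panel, buffer_kb=10)
counts = assignment.counts
print(f"partition at 10 kb: {counts}")
print("coding = SNPs inside gene-set genes; buffer = within 10 kb of their "
      "ends; rest = everything else. The three labels are exclusive and "
      "cover every SNP, as the variance partitioning requires.")
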