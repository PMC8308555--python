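"""Genotype QC and the per-SNP exposure association scan.

QC removes variants by missingness (>1%), monomorphism and
Hardy-Weinberg disequilibrium (p < 1e-6), in that order; the linear
scan then regresses log-Hcy on each dosage, adjusted for age, sex and
area.
"""

from hcymr import SimConfig, linear_assoc, qc_filter, simulate_cohort

config = SimConfig(
    n_samples=6000,
    variants=[(f"snp{i}", "A", "G", f) for i, f in
              enumerate([0.3, 0.4, 0.2, 0.35, 0.45])],
    beta_exposure=[0.06, 0.05, 0.04, 0.0, 0.0],
    missing_rate=0.005,
    seed=7,
)
genotypes, pheno = simulate_cohort(config)

filtered, report = qc_filter(genotypes)
print(f"QC: {report.n_input} in, {report.n_retained} retained "
      f"(missing {report.n_removed_missingness}, monomorphic "
      f"{report.n_removed_monomorphic}, HWE {report.n_removed_hwe})")

stats = linear_assoc(filtered, pheno["log_hcy"],
                     pheno[["age", "sex", "area"]])
print(stats[["snp_id", "beta", "se", "p"]].round(4).to_string(index=False))

# The three causal SNPs surface with betas near their generative values
# (0.06, 0.05, 0.04 log-umol/L per allele) and tiny p-values; the two
# null SNPs hover near beta = 0.
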