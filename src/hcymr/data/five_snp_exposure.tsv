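# Five-SNP genetic-instrument fixture for the homocysteine -> metabolic
# syndrome analysis. Exposure betas/SEs/p are per effect-allele copies on
# natural-log homocysteine in the KARE cohort (n=5902, adjusted for age,
# sex, area). Outcome rows carry log-OR of MetS per allele in the merged
# HEXA+CAVAS cohorts (n=5509): beta = ln(OR) and se derived from the
# printed 95% CI as (ln(hi) - ln(lo)) / (2 * 1.959964).
# SYNTHETIC fields: the non-effect (other) alleles are NOT published and
# are placeholder assignments chosen to be non-palindromic.
snp_id	effect_allele	other_allele	beta	se	p	n	trait	chrom	gene
rs12567136	A	G	-0.058	0.008	3.23e-10	5902	exposure	1	CLCN6
rs1801133	G	A	-0.039	0.005	2.74e-17	5902	exposure	1	MTHFR
rs2336377	G	A	-0.045	0.008	1.74e-08	5902	exposure	1	LOC390997
rs1624230	C	T	-0.027	0.005	3.81e-08	5902	exposure	3	KNG1
rs1836883	T	C	0.029	0.005	9.55e-10	5902	exposure	11	NOX4
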