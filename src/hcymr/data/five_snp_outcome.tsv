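# Five-SNP genetic-instrument fixture for the homocysteine -> metabolic
# syndrome analysis. Exposure betas/SEs/p are per effect-allele copies on
# natural-log homocysteine in the KARE cohort (n=5902, adjusted for age,
# sex, area). Outcome rows carry log-OR of MetS per allele in the merged
# HEXA+CAVAS cohorts (n=5509): beta = ln(OR) and se derived from the
# printed 95% CI as (ln(hi) - ln(lo)) / (2 * 1.959964).
# SYNTHETIC fields: the non-effect (other) alleles are NOT published and
# are placeholder assignments chosen to be non-palindromic.
snp_id	effect_allele	other_allele	beta	se	p	n	trait	chrom	gene	or_	ci_low	ci_high
rs12567136	A	G	-0.002002	0.011249	0.867	5509	outcome	1	CLCN6	0.998	0.976	1.02
rs1801133	G	A	-0.052346	0.056084	0.354	5509	outcome	1	MTHFR	0.949	0.85	1.059
rs2336377	G	A	0.004988	0.008631	0.577	5509	outcome	1	LOC390997	1.005	0.988	1.022
rs1624230	C	T	-0.002002	0.008440	0.774	5509	outcome	3	KNG1	0.998	0.981	1.014
rs1836883	T	C	-0.017146	0.008050	0.031	5509	outcome	11	NOX4	0.983	0.967	0.998
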