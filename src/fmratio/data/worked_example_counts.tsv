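# Worked-example count table (GRCh38 coordinates).
# The rs201580891 row carries the published gnomAD exome counts for the FMR1
# variant that is observed only in heterozygous females (18,736 female minor
# alleles out of 104,056; zero male carriers out of 38,527 genotyped male X
# chromosomes); its position is a placeholder inside the FMR1 locus.
# All syn_* rows are synthetic no-sex-effect variants added so that each region
# class (PAR1, PAR2, non-PAR X, autosome) is represented.
variant_id	chrom	pos	ref	alt	v_f	a_f	v_m	a_m	hom_f	hemi_m	qc_fail
rs201580891	X	147912050	G	C	18736	104056	0	38527	0	0	yes
syn_par1_null	X	1000000	A	G	520	100000	498	100000	2		no
syn_par2_null	X	155800000	C	T	30	100000	28	99000	0		no
syn_nonparx_null	X	50000000	T	A	40	100000	18	50000	0	18	no
syn_chr21_null	21	10450000	G	A	100	120000	95	110000	0		no
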