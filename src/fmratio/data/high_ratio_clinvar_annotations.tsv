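# Annotation evidence for the 25 ClinVar-annotated high-ratio (R > 11) variants
# from the gnomAD exome X-chromosome screen. Columns: ClinVar significance class,
# QC status in the independent gnomAD genomes dataset, published female-to-male
# allele proportion ratio, total observation count, OMIM gene-phenotype link
# category, and VENUS protein-structure effect call.
variant_id	gene	clinvar_class	qc_fail_genomes	ratio	n_observations	omim_link	structural_prediction
rs201580891	FMR1	LIKELY_BENIGN	yes	6937.5	18736	SPECIFIC	NEUTRAL
rs1315062158	IQSEC	BENIGN_OR_LIKELY_BENIGN	yes	1809.3	3617	SPECIFIC	NOT_APPLICABLE
rs782666190	SMC1A	BENIGN	yes	929.4	4418	SPECIFIC	NOT_APPLICABLE
rs1432363549	SMC1A	LIKELY_BENIGN	yes	487.7	968	SPECIFIC	NOT_APPLICABLE
rs782705493	HDAC8	BENIGN	yes	379.3	1657	SPECIFIC	NOT_APPLICABLE
rs777010333	COL4A6	LIKELY_BENIGN	yes	279.1	563	SPECIFIC	NOT_APPLICABLE
rs782664878	SMC1A	BENIGN	yes	263.8	8386	SPECIFIC	NOT_APPLICABLE
rs372580592	SLC9A6	LIKELY_BENIGN	yes	223.1	493	SPECIFIC	NOT_APPLICABLE
rs782792601	NDUFB11	BENIGN	yes	201.2	624	SPECIFIC	NOT_APPLICABLE
rs782032695	EBP	LIKELY_BENIGN	yes	194.5	398	SPECIFIC	NOT_APPLICABLE
rs781824575	HDAC8	BENIGN	yes	131.5	6367	SPECIFIC	NOT_APPLICABLE
rs745354475	USP9X	BENIGN	yes	129.4	432	SPECIFIC	NOT_APPLICABLE
rs199626569	GJB1	UNCERTAIN	not_assessed	89.3	1761	SPECIFIC	NEUTRAL
rs782072345	NDUFB11	BENIGN	no	87.6	1340	SPECIFIC	NOT_APPLICABLE
rs745338783	POLA1	LIKELY_BENIGN	yes	87.1	2011	SPECIFIC	NOT_APPLICABLE
rs751314374	RPGR	CONFLICTING	yes	70.7	308	SPECIFIC	NEUTRAL
rs1250133030	RPGR	LIKELY_BENIGN	yes	64.9	318	SPECIFIC	UNCLEAR
rs72609545	VCX3A	BENIGN	yes	58.1	1218	TENTATIVE	NEUTRAL
rs12849277	MED12	BENIGN_OR_LIKELY_BENIGN	yes	55.2	83	SPECIFIC	NOT_APPLICABLE
rs781379769	USP9X	BENIGN_OR_LIKELY_BENIGN	yes	53.3	660	SPECIFIC	NOT_APPLICABLE
rs145404090	SAGE1	UNCERTAIN	yes	44.8	79	TENTATIVE	NEUTRAL
rs148934011	RBMX	UNCERTAIN	yes	33.6	56	SPECIFIC	STABILIZING
rs782233695	RHOXF2	LIKELY_BENIGN	yes	22.7	39	NONE	UNCLEAR
rs1446705794	RPGR	LIKELY_BENIGN	yes	20.9	91	SPECIFIC	NOT_APPLICABLE
rs201558029	DMD	BENIGN	no	15.7	26	SPECIFIC	NOT_APPLICABLE
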