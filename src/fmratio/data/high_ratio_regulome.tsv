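# RegulomeDB evidence for the 25 ClinVar-annotated high-ratio variants from the
# gnomAD exome X-chromosome screen. rank: integrative evidence category (1a =
# strongest, 7 = no evidence); score: transcription-factor-binding model
# probability of regulatory function in [0, 1].
variant_id	regulome_rank	regulome_score
rs201580891	7	0.18412
rs1315062158	5	0.38000
rs782666190	5	0.00454
rs1432363549	5	0.00000
rs782705493	2b	0.73553
rs777010333	5	0.01895
rs782664878	5	0.00000
rs372580592	5	0.09659
rs782792601	4	0.70497
rs782032695	2b	0.48000
rs781824575	2b	0.79371
rs745354475	5	0.00000
rs199626569	4	0.60906
rs782072345	4	0.70497
rs745338783	5	0.00125
rs751314374	5	0.58955
rs1250133030	5	0.58955
rs72609545	5	0.58955
rs12849277	5	0.58955
rs781379769	5	0.00000
rs145404090	5	0.23589
rs148934011	5	0.58955
rs782233695	4	0.60906
rs1446705794	5	0.98500
rs201558029	7	0.18412
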