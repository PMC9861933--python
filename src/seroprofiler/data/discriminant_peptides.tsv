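mz	p_value	accession	flanked_peptide	protein_name
1077.88	0.0158	CC50A_HUMAN	R.NSSNTADITI.-	Cell cycle control protein 50A
1419.92	0.0139	TX13B_HUMAN	K.EACTWGSLALGVR.F	Testis-expressed sequence 13B
2012.59	0.00467	DEN5A_HUMAN	K.LNTGQIQESIGEAVNGIVK.H	DENN domain-containing protein 5A
2601.66	0.00194	SKOR2_HUMAN	K.AGGGSYHHSSAFRPVGGKDDAESLAK.L	SKI family transcriptional corepressor 2
2661.39	0.532	SPAG6_HUMAN	R.LPGIMMLGYVAAHSENLAMAVIISK.G	Sperm-associated antigen 6
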