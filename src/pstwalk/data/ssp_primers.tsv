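id	sequence	orientation	target_note	nested_parent	tm_printed	cg_printed	lc_printed
5315	CTSAAGCGGATCGAGAACAAGATCAACC	F	exon 1		61.5	50.0	78
5410	CTCATCATCTTCTCCACCAAGGGAAAGCTCTACGAGTTC	F	exon 1		66.2	48.7	81
5299	GTTCTCGATCCGCTTSAGCTGCACCTT	R	exon 1		64.5	55.6	89
5411	GCACGGAGATCTCGTGCGCCTTCTTGAG	R	exon 1		66.8	60.7	89
5412	CTCGTAGAGCTTTCCCTTGGTGGAGAAGATGATGAG	R	exon 1		65.3	50.0	80
5317	ARCGGTAYGAGCGYTACTCYTATGCAGA	F	exon 2		62.3	50.0	87
5413	GARCGGTATGAGCGCTAYTCYTATGCAGA	F	exon 2		62.4	50.0	83
5300	TARGAGTARCGCTCRTACCGYTCAAGAA	R	exon 2		60.5	46.4	83
5301	GTARCGCTCRTACCGYTCAAGAATTTTGTCCATA	R	exon 2		62.8	42.6	88
5416	CAGCCGTTGATGTGGCTCACCATCCA	R	exon 8		64.7	57.7	93
5445	CTTGTTTTGGGCCGTCTCGCTTC	R	promoter		61.2	56.5	73
5446	CGTCTCGCTTCTCCCGTTTGGGCAT	R	promoter	5445	64.9	60.0	81
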