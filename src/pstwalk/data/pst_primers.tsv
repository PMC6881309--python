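id	adapter	n_len	palindrome	enzyme	tm_printed	cg_printed	lc_printed
5601	GTTGCGGCAGGTCCTCACC	10	GACGTC	AatII	49.3	56.3	100
5602	GTTGCGGCAGGTCCTCACC	10	AACGTT	AclI	46.1	43.8	100
5603	GTTGCGGCAGGTCCTCACC	10	TTCGAA	AsuII	45.6	43.8	100
5604	GTTGCGGCAGGTCCTCACC	10	TGGCCA	BalI	51.0	56.3	100
5605	GTTGCGGCAGGTCCTCACC	10	GGATCC	BamHI	48.3	56.3	100
5606	GTTGCGGCAGGTCCTCACC	10	TGATCA	BclI	44.7	43.8	100
5326	GTTGCGGCAGGTCCTCACC	10	AGATCT	BglII	43.7	43.8	100
5607	GTTGCGGCAGGTCCTCACC	10	ATCGAT	ClaI	44.8	43.8	89
5608	GTTGCGGCAGGTCCTCACC	10	GAATTC	EcoRI	43.7	43.8	100
5609	GTTGCGGCAGGTCCTCACC	10	GATATC	EcoRV	42.3	43.8	89
5610	GTTGCGGCAGGTCCTCACC	10	AAGCTT	HindIII	45.5	43.8	100
5611	GTTGCGGCAGGTCCTCACC	10	GTTAAC	HpaI	43.6	43.8	100
5612	GTTGCGGCAGGTCCTCACC	10	GGTACC	KpnI	48.2	56.3	100
5613	GTTGCGGCAGGTCCTCACC	10	CCATGG	NcoI	49.1	56.3	100
5614	GTTGCGGCAGGTCCTCACC	10	GCTAGC	NheI	49.3	56.3	89
5615	GTTGCGGCAGGTCCTCACC	10	CACGTG	PmaCI	50.2	56.3	100
5616	GTTGCGGCAGGTCCTCACC	10	CTGCAG	PstI	49.7	56.3	100
5617	GTTGCGGCAGGTCCTCACC	10	CAGCTG	PvuII	49.7	56.3	100
5618	GTTGCGGCAGGTCCTCACC	10	GAGCTC	SacI	48.8	56.3	100
5619	GTTGCGGCAGGTCCTCACC	10	GTCGAC	SalI	49.3	56.3	100
5620	GTTGCGGCAGGTCCTCACC	10	AGTACT	ScaI	43.7	43.8	100
5621	GTTGCGGCAGGTCCTCACC	10	GCATGC	SphI	50.9	56.3	89
5622	GTTGCGGCAGGTCCTCACC	10	AGGCCT	StuI	50.1	56.3	100
5327	GTTGCGGCAGGTCCTCACC	10	TCTAGA	XbaI	43.1	43.8	100
5623	GTTGCGGCAGGTCCTCACC	10	CTCGAG	XhoI	48.6	56.3	100
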