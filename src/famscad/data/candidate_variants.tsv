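chrom	pos	ref	alt	gene	consequence	maf	cadd_phred	hgmd	fathmm_xf	regdb_rank	pwm	site_context
chr20	61851254	T	C	CDH4	missense	0.000004	25.1	.	.	.	.	.
chr2	188994187	C	T	COL3A1	missense	0.000004	32	.	.	.	.	.
chr13	110424391	C	T	COL4A1	missense	0.0003	29.4	CM1818194	.	.	.	.
chr13	110512122	G	A	COL4A2	missense	0.00002	24.8	.	.	.	.	.
chr13	110560855	G	A	COL4A2	missense	0.00001	26.6	.	.	.	.	.
chr2	189134501	A	C	COL5A2	missense	NR	27.5	.	.	.	.	.
chr3	41224610	A	G	CTNNB1	missense	0.0009	21.2	CM043757	.	.	.	.
chr7	100804815	G	A	EPHB4	missense	0.0003	24.8	.	.	.	.	.
chr15	90981842	A	G	IQGAP1	missense	NR	27.7	.	.	.	.	.
chr2	26524783	CCGCGCGCTGCTCAC	C	KCNK3	frameshift	NR	.	.	.	.	.	.
chr2	169127394	T	A	LRP2	missense	NR	24.6	.	.	.	.	.
chr9	136505484	C	T	NOTCH1	missense	0.0006	34	.	.	.	.	.
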