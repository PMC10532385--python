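gene	pli	oe_lof	mis_z	rank_coronary	rank_aorta	rank_tibial	ctd_aor_panel	mgi	hgmd_vasc	gwas_trait	ppi_talin1	ppi_gwas
CDH4	.	.	2.02	47	46	43	0	0	0	1	0	1
COL3A1	.	.	4.09	6	5	7	1	1	1	0	1	1
COL4A1	.	.	3.02	1	3	2	0	1	1	1	1	1
COL4A2	.	.	2.19	2	1	3	0	1	1	1	1	1
COL5A2	.	.	2.44	6	4	8	1	1	1	0	1	1
CTNNB1	.	.	3.85	13	15	3	0	1	0	0	1	1
EPHB4	.	.	2.30	30	37	38	0	1	1	0	0	0
IQGAP1	.	.	2.44	5	4	3	0	0	1	0	1	1
KCNK3	0.90	.	.	5	13	7	0	0	1	1	0	0
LRP2	.	.	2.07	35	31	34	0	1	1	0	0	1
NOTCH1	.	.	3.45	26	28	22	1	1	1	1	1	1
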