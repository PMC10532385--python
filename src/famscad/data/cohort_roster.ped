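# Familial SCAD cohort, one row per individual.
# Columns: family_id individual_id father_id mother_id sex affection [features] [event_ages]
# sex: 1=male 2=female 0=unknown; affection: 0=unknown 1=unaffected 2=SCAD 3=other arteriopathy
# Individuals without a published row (unaffected connecting relatives) are inferred
# from family structure; generation labels for SCAD-08/-09/-11 are approximate.
SCAD-01	I.1	0	0	1	1	.	.
SCAD-01	I.2	0	0	2	1	.	.
SCAD-01	II.1	I.1	I.2	2	2	SCAD,MH	42
SCAD-01	II.2	I.1	I.2	2	2	SCAD,FMD,P,ES	47
SCAD-02	I.1	0	0	1	1	.	.
SCAD-02	I.2	0	0	2	1	.	.
SCAD-02	II.1	I.1	I.2	2	2	SCAD,CT,ES	35
SCAD-02	II.2	I.1	I.2	2	2	SCAD	45
SCAD-03	I.1	0	0	1	1	.	.
SCAD-03	I.2	0	0	2	1	.	.
SCAD-03	II.1	I.1	I.2	2	2	SCAD,FMD,CT	43
SCAD-03	II.2	I.1	I.2	2	2	SCAD,MH	45
SCAD-04	I.1	0	0	1	1	.	.
SCAD-04	I.2	0	0	2	1	.	.
SCAD-04	II.1	I.1	I.2	2	2	SCAD,ES	43
SCAD-04	II.2	I.1	I.2	2	2	SCAD	59
SCAD-05	I.1	0	0	1	1	.	.
SCAD-05	I.2	0	0	2	1	.	.
SCAD-05	II.1	I.1	I.2	2	2	SCAD,FMD,P,PE	34
SCAD-05	II.2	I.1	I.2	2	2	SCAD,FMD	36
SCAD-06	I.1	0	0	1	1	.	.
SCAD-06	I.2	0	0	2	1	.	.
SCAD-06	II.1	I.1	I.2	2	2	SCAD,FMD,ICAA	50
SCAD-06	II.2	I.1	I.2	1	2	SCAD	47
SCAD-06	II.3	I.1	I.2	1	3	SMAD	40
SCAD-07	I.1	0	0	1	1	.	.
SCAD-07	I.2	0	0	2	1	.	.
SCAD-07	II.1	0	0	1	1	.	.
SCAD-07	II.2	I.1	I.2	2	1	.	.
SCAD-07	II.3	I.1	I.2	2	3	CA,ICAA	65
SCAD-07	III.1	II.1	II.2	2	2	SCAD,FMD,ES,CA	41
SCAD-07	III.2	II.1	II.2	2	2	SCAD,FMD,CT	37
SCAD-08	I.1	0	0	1	3	CA	71
SCAD-08	I.2	0	0	2	1	.	.
SCAD-08	II.1	I.1	I.2	2	1	.	.
SCAD-08	II.1s	0	0	1	1	.	.
SCAD-08	II.2	I.1	I.2	2	1	.	.
SCAD-08	II.2s	0	0	1	1	.	.
SCAD-08	III.1	II.1s	II.1	2	2	SCAD,R,ES	50,59
SCAD-08	III.2	II.2s	II.2	2	2	SCAD,CT	50
SCAD-09	II.1	0	0	1	1	.	.
SCAD-09	II.2	0	0	2	1	.	.
SCAD-09	III.1	II.1	II.2	1	3	CVA	25
SCAD-09	III.2	II.1	II.2	2	2	SCAD,ES	42
SCAD-09	III.3	II.1	II.2	2	2	SCAD,FMD	.
SCAD-10	I.1	0	0	1	1	.	.
SCAD-10	I.2	0	0	2	1	.	.
SCAD-10	II.2	I.1	I.2	2	3	CT	.
SCAD-10	II.2s	0	0	1	1	.	.
SCAD-10	II.3	I.1	I.2	2	2	SCAD,R,ES	42,45,56
SCAD-10	III.1	II.2s	II.2	2	2	SCAD,MH	39
SCAD-11	I.1	0	0	1	1	.	.
SCAD-11	I.2	0	0	2	1	.	.
SCAD-11	II.1	I.1	I.2	2	1	.	.
SCAD-11	II.1s	0	0	1	1	.	.
SCAD-11	II.2	I.1	I.2	2	1	.	.
SCAD-11	II.2s	0	0	1	1	.	.
SCAD-11	III.1	II.1s	II.1	2	2	SCAD,FMD	36
SCAD-11	III.2	II.2s	II.2	2	2	SCAD,CT,MH,PE	44
SCAD-12	I.1	0	0	1	1	.	.
SCAD-12	I.2	0	0	2	1	.	.
SCAD-12	II.1	I.1	I.2	2	3	CA	.
SCAD-12	II.3	I.1	I.2	2	2	SCAD,FMD	47
SCAD-12	II.3s	0	0	1	1	.	.
SCAD-12	III.1	II.3s	II.3	2	2	SCAD,P	38
SCAD-13	I.1	0	0	1	1	.	.
SCAD-13	I.2	0	0	2	2	SCAD	54
SCAD-13	II.1	I.1	I.2	2	2	SCAD	44
SCAD-13	II.2	I.1	I.2	2	3	CD	45
SCAD-14	I.1	0	0	1	1	.	.
SCAD-14	I.2	0	0	2	2	SCAD,FMD,R	59,61
SCAD-14	II.1	I.1	I.2	2	2	SCAD,PE	32
SCAD-15	I.1	0	0	2	3	AAA,IAA,PAA	65
SCAD-15	I.2	0	0	1	1	.	.
SCAD-15	II.1	I.2	I.1	2	2	SCAD,FMD,MH	33
SCAD-15	II.2	I.2	I.1	2	2	SCAD	.
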