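gene	protein_change	n_patients	hla_alleles	n_neoantigens	n_icgc
BRCA2	I27V	1	B*58:01;C*03:02;C*08:01	6	0
BRCA2	S37L	1	B*15:02;B*58:01;C*03:02	6	1
BRCA2	V144F	1	B*15:02;C*03:02	5	0
BRCA2	Q147R	1	A*33:03	2	0
BRCA2	D156E	1	A*11:01	1	0
BRCA2	N289H	1	A*02:01;C*03:02	5	3
BRCA2	T2542M	1	C*14:02	2	0
FAT4	Q453L	1	A*02:01;C*03:02	12	5
FAT4	V462E	1	B*40:01;B*58:01;C*03:02	11	0
FAT4	D598Y	1	A*02:01;B*15:01	5	0
FAT4	A807V	1	A*02:01;B*40:01;B*58:01;C*03:02	13	6
GNAQ	D95Y	1	A*24:10;B*18:02;B*39:01;C*07:02	8	0
GNAQ	T96S	3	A*02:01;A*03:01;A*11:01;B*15:01;B*39:01	25	10
LRP1B	H4368Q	1	A*11:02	1	0
LRP1B	L1995M	1	C*03:04	1	0
LRP1B	R3026S	1	A*03:01;B*15:01	3	0
LRP1B	R4062K	1	A*11:01;A*33:03;C*03:02	8	0
LRP1B	T2206I	1	A*02:01	1	0
PIK3CA	G106C	1	A*03:01;A*11:01	2	0
PIK3CA	H1047Y	1	B*15:01	1	8
PIK3CA	V344M	1	A*03:01;A*11:01;C*14:02	4	5
PREX2	E1428K	1	A*30:01	2	0
PREX2	H895Q	1	B*15:01;C*03:03	3	0
PREX2	Q102H	1	B*15:01	1	0
PREX2	S1488L	1	A*02:01;A*33:03;B*40:01;C*07:02	10	0
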