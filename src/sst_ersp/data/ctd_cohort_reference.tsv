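participant	diagnosis	age	sex	handedness	ygtss_total_tic	puts_total	dupaul_adhd	cybocs	medications
1	TS	13	M	L	30	19	21	0	citalopram, gabapentin
2	TS	14	F	R	22	11	15	1	none
3	TS	11	M	R	8	18	5	0	none
4	TS	14	M	R	21	26	11	0	none
5	TS	11	M	R	17	19	13	0	none
6	TS	12	M	R	36	16	18	16	citalopram, clonidine, risperidone
7	TS	15	M	R	42	21	40	21	atomoxetine, fluvoxamine
8	TS	14	M	R	23	29	21	0	guanfacine, sertraline
9	TS	11	M	R	20	23	22	0	none
10	CMTD	11	F	R	12	19	4	0	none
11	TS	16	M	R	14	28	29	22	desvenlafaxine
12	TS	15	F	R	30	31	30	22	none
13	TS	16	M	R	24	15	0	18	none
14	TS	13	M	R	28	27	13	0	none
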