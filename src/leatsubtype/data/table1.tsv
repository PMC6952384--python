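patient	sex	age	engel	diagnosis	fcd	hippocampal_sclerosis	who_grade	cd34	idh	mib	dead	recurrence	cluster
1	F	42	Ia	DNT	no	no	I	negative	WT	2-5%	no	no	1
2	M	28	Ia	DNT	no	no	I	positive	WT	1%	no	no	1
3	M	10	IIIa	DNT	no	no	I	positive	WT	5%	no	yes	1
4	M	48	Ia	DNT	no	no	I	negative	WT	NA	no	no	1
5	M	70	Ia	DNT	no	no	I	NA	WT	<1%	no	no	1
6	M	15	Ia	DNT	no	no	I	negative	WT	<1%	no	no	1
7	M	12	Ia	DNT	no	no	I	positive	WT	<1%	no	no	1
8	M	14	Ia	PXA	no	no	II	positive	WT	11-20%	no	yes	2
9	M	25	Ia	GG	no	no	I	negative	WT	2-5%	no	yes	2
10	F	27	Ia	GG	no	no	I	positive	WT	2-5%	no	no	2
11	F	16	Ia	GG	no	no	I	positive	WT	<1%	no	no	2
12	M	27	Ia	GG	no	no	I	positive	WT	<1%	no	no	2
13	F	20	IIIa	PXA	no	no	III	negative	WT	20%	no	yes	2
14	M	16	Ia	DNT	no	no	I	negative	WT	2-5%	no	no	4
15	M	41	Ia	GG	no	no	I	negative	WT	1%	no	no	4
16	F	33	Ia	GG	no	no	I	positive	WT	<1%	no	no	4
17	M	20	Ia	DNT	no	no	I	positive	WT	<1%	no	no	4
18	M	17	Ia	DNT	no	no	I	positive	WT	<1%	no	no	4
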