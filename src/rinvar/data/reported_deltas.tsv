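label	group	subgroup	region	delta_b_ct
I136V	GF	IEM	VSD(S1;DI)	0.12
S211P	GF	IEM	VSD(S4;DI)	-1.09
F216S	GF	IEM	VSD(S4;DI)	-1.71
L823R	GF	IEM	VSD(S4;DII)	1.23
W1538R	GF	IEM	VSD(S2-S3;DIV)	0.18
I234T	GF	IEM	S4-S5(DI)	2.33
S241T	GF	IEM	S4-S5(DI)	0.34
I848T	GF	IEM	S4-S5(DII)	-5.83
L858H	GF	IEM	S4-S5(DII)	-1.85
L858F	GF	IEM	S4-S5(DII)	-1.74
G856D	GF	IEM	S4-S5(DII)	-0.55
A863P	GF	IEM	S4-S5(DII)	-0.32
P1308L	GF	IEM	S4-S5(DIII)	0.04
V1316A	GF	IEM	S4-S5(DIII)	0.36
A1632E	GF	IEM	S4-S5(DIV)	0.27
N395K	GF	IEM	Pore(S6;DI)	5.32
V400M	GF	IEM	Pore(S6;DI)	-0.68
V872G	GF	IEM	Pore(S5;DI)	-2.48
F1449V	GF	IEM	Pore(S6;DIII)	-0.51
A1746G	GF	IEM	Pore(S6;DIV)	1.40
R185H	GF	SFN	VSD(S2-S3;DI)	0
I228M	GF	SFN	VSD(S4;DI)	2.04
I739V	GF	SFN	VSD(S1;DII)	0.54
M1532I	GF	SFN	VSD(S2-S3;DIV)	0.15
M932L	GF	SFN	Loop-P(DII)	0.46
V1298D	GF	PEPD	S4-S5(DIII)	-0.81
V1298F	GF	PEPD	S4-S5(DIII)	-0.004
V1299F	GF	PEPD	S4-S5(DIII)	0.07
G1607R	GF	PEPD	S4-S5(DIII)	0.62
M1627K	GF	PEPD	S4-S5(DIV)	1.22
S126A	CONTROL	hSNP	VSD(S1;DI)	0
L127A	CONTROL	hSNP	VSD(S1;DI)	0.12
M145L	CONTROL	hSNP	VSD(S1;DI)	0
N146S	CONTROL	hSNP	VSD(S1;DI)	0.020
V194I	CONTROL	hSNP	VSD(S3;DI)	-0.14
L201V	CONTROL	hSNP	VSD(S2;DI)	0.259
N206D	CONTROL	hSNP	VSD(S2;DI)	-0.037
E759D	CONTROL	hSNP	VSD(S1-S2;DII)	-0.18
A766T	CONTROL	hSNP	VSD(S2;DII)	0.20
A766V	CONTROL	hSNP	VSD(S2;DII)	0.06
I767V	CONTROL	hSNP	VSD(S2;DII)	0.13
V795I	CONTROL	hSNP	VSD(S3;DII)	-0.72
A815S	CONTROL	hSNP	VSD(S3-S4;DII)	0.24
K1176R	CONTROL	hSNP	VSD(S1;DIII)	0.0004
R1207K	CONTROL	hSNP	VSD(S1-S2;DIII)	-0.19
T1210N	CONTROL	hSNP	VSD(S1-S2;DIII)	0
I1235V	CONTROL	hSNP	VSD(S2;DIII)	0
A1505V	CONTROL	hSNP	VSD(S1;DIV)	0.00026
S1509T	CONTROL	hSNP	VSD(S1;DIV)	0.092
S1509A	CONTROL	hSNP	VSD(S1;DIV)	0.0084
Q1530P	CONTROL	hSNP	VSD(S1-S2;DIV)	-0.166
Q1530K	CONTROL	hSNP	VSD(S1-S2;DIV)	0.20
Q1530D	CONTROL	hSNP	VSD(S1-S2;DIV)	0.066
H1531Y	CONTROL	hSNP	VSD(S1-S2;DIV)	0.12
M1532V	CONTROL	hSNP	VSD(S1-S2;DIV)	0.66
E1534D	CONTROL	hSNP	VSD(S1-S2;DIV)	0.067
Y1537N	CONTROL	hSNP	VSD(S1-S2;DIV)	0.63
T1548S	CONTROL	hSNP	VSD(S2;DIV)	0.085
H1560Y	CONTROL	hSNP	VSD(S2-S3;DIV)	-0.20
H1560C	CONTROL	hSNP	VSD(S2-S3;DIV)	0.17
V1565I	CONTROL	hSNP	VSD(S2-S3;DIV)	-0.45
I1577L	CONTROL	hSNP	VSD(S3;DIV)	-0.07
D1586E	CONTROL	hSNP	VSD(S3;DIV)	0.07
T1590K	CONTROL	hSNP	VSD(S3-S4;DIV)	0.07
T1590R	CONTROL	hSNP	VSD(S3-S4;DIV)	0.29
V1613I	CONTROL	hSNP	VSD(S4;DIV)	-0.67
N1245S	CONTROL	nABN	VSD(S2-S3;DIII)	-0.05
L1267V	CONTROL	nABN	VSD(S3;DIII)	0
V1428I	CONTROL	nABN	Pore(S6;DIII)	0.19
T920N	CONTROL	nABN	Loop-P(DII)	0.04
D890E	CONTROL	hSNP	Loop-P(DII)	-0.13
D890V	CONTROL	hSNP	Loop-P(DII)	-0.13
T1398M	CONTROL	hSNP	Loop-P(DIII)	-0.14
I1399D	CONTROL	hSNP	Loop-P(DIII)	-1.63
D1411S	CONTROL	hSNP	Loop-P(DIII)	-0.20
D1411N	CONTROL	hSNP	Loop-P(DIII)	-0.16
K1412I	CONTROL	hSNP	Loop-P(DIII)	-0.0033
K1412E	CONTROL	hSNP	Loop-P(DIII)	-0.067
K1415I	CONTROL	hSNP	Loop-P(DIII)	0.038
S1419N	CONTROL	hSNP	Loop-P(DIII)	0.001
D1662A	CONTROL	hSNP	Loop-P(DIV)	-0.43
G1674A	CONTROL	hSNP	Loop-P(DIV)	-0.71
K1700A	CONTROL	hSNP	Loop-P(DIV)	-0.22
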