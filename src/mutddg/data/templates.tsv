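res	atom	a1	a2	a3	bond	angle	torsion
ALA	CB	CA	N	C	1.529	109.46	-120.00
ARG	CB	CA	N	C	1.536	111.55	-123.56
ARG	CG	CB	CA	N	1.537	114.54	chi1
ARG	CD	CG	CB	CA	1.527	112.42	chi2
ARG	NE	CD	CG	CB	1.444	111.02	chi3
ARG	CZ	NE	CD	CG	1.406	123.00	chi4
ARG	NH1	CZ	NE	CD	1.391	121.00	179.99
ARG	NH2	CZ	NE	CD	1.391	119.81	-0.01
ASN	CB	CA	N	C	1.531	109.45	-120.00
ASN	CG	CB	CA	N	1.507	109.48	chi1
ASN	OD1	CG	CB	CA	1.213	119.97	chi2
ASN	ND2	CG	CB	CA	1.348	120.01	chi2-179.93
ASP	CB	CA	N	C	1.530	109.48	-120.01
ASP	CG	CB	CA	N	1.508	109.46	chi1
ASP	OD1	CG	CB	CA	1.208	119.96	chi2
ASP	OD2	CG	CB	CA	1.341	120.00	chi2-179.94
CYS	CB	CA	N	C	1.528	109.50	-120.01
CYS	SG	CB	CA	N	1.814	109.50	chi1
GLN	CB	CA	N	C	1.529	109.46	-120.07
GLN	CG	CB	CA	N	1.528	109.53	chi1
GLN	CD	CG	CB	CA	1.507	109.54	chi2
GLN	OE1	CD	CG	CB	1.212	119.94	chi3
GLN	NE2	CD	CG	CB	1.347	120.09	chi3-179.96
GLU	CB	CA	N	C	1.530	109.48	-119.96
GLU	CG	CB	CA	N	1.531	109.40	chi1
GLU	CD	CG	CB	CA	1.508	109.43	chi2
GLU	OE1	CD	CG	CB	1.208	120.00	chi3
GLU	OE2	CD	CG	CB	1.343	120.00	chi3-179.94
HIS	CB	CA	N	C	1.534	111.13	-122.78
HIS	CG	CB	CA	N	1.510	112.98	chi1
HIS	ND1	CG	CB	CA	1.351	120.33	chi2
HIS	CD2	CG	CB	CA	1.338	129.93	chi2+179.85
HIS	CE1	ND1	CG	CB	1.337	107.86	179.90
HIS	NE2	CE1	ND1	CG	1.337	107.62	-0.04
ILE	CB	CA	N	C	1.529	109.43	-120.07
ILE	CG1	CB	CA	N	1.529	109.55	chi1
ILE	CG2	CB	CA	N	1.530	109.46	chi1-119.97
ILE	CD1	CG1	CB	CA	1.529	109.55	chi2
LEU	CB	CA	N	C	1.529	109.42	-119.97
LEU	CG	CB	CA	N	1.530	109.49	chi1
LEU	CD1	CG	CB	CA	1.530	109.50	chi2
LEU	CD2	CG	CB	CA	1.529	109.50	chi2+120.09
LYS	CB	CA	N	C	1.530	109.45	-119.97
LYS	CG	CB	CA	N	1.531	109.42	chi1
LYS	CD	CG	CB	CA	1.531	109.44	chi2
LYS	CE	CD	CG	CB	1.529	109.46	chi3
LYS	NZ	CE	CD	CG	1.469	109.50	chi4
MET	CB	CA	N	C	1.529	109.43	-120.04
MET	CG	CB	CA	N	1.528	109.54	chi1
MET	SD	CG	CB	CA	1.814	109.51	chi2
MET	CE	SD	CG	CB	1.814	100.03	chi3
PHE	CB	CA	N	C	1.529	109.47	-120.09
PHE	CG	CB	CA	N	1.505	109.52	chi1
PHE	CD1	CG	CB	CA	1.382	120.06	chi2
PHE	CD2	CG	CB	CA	1.383	120.00	chi2+179.76
PHE	CE1	CD1	CG	CB	1.382	120.03	179.99
PHE	CE2	CD2	CG	CB	1.382	119.98	179.84
PHE	CZ	CE1	CD1	CG	1.381	120.05	-0.05
PRO	CB	CA	N	C	1.543	104.72	-118.84
PRO	CG	CB	CA	N	1.543	105.06	chi1
PRO	CD	CG	CB	CA	1.544	105.06	chi2
SER	CB	CA	N	C	1.529	109.47	-120.02
SER	OG	CB	CA	N	1.428	109.51	chi1
THR	CB	CA	N	C	1.529	109.41	-120.00
THR	OG1	CB	CA	N	1.428	109.51	chi1
THR	CG2	CB	CA	N	1.530	109.53	chi1-120.03
TRP	CB	CA	N	C	1.529	109.52	-120.03
TRP	CG	CB	CA	N	1.507	109.44	chi1
TRP	CD1	CG	CB	CA	1.343	126.50	chi2
TRP	CD2	CG	CB	CA	1.464	126.51	chi2+179.62
TRP	NE1	CD1	CG	CB	1.369	109.93	179.94
TRP	CE2	NE1	CD1	CG	1.377	109.85	-0.06
TRP	CE3	CD2	CG	CD1	1.396	134.05	-179.53
TRP	CZ2	CE2	NE1	CD1	1.391	133.51	-180.00
TRP	CZ3	CE3	CD2	CG	1.366	119.80	179.64
TRP	CH2	CZ2	CE2	NE1	1.377	119.81	-179.97
TYR	CB	CA	N	C	1.529	109.47	-120.04
TYR	CG	CB	CA	N	1.506	109.50	chi1
TYR	CD1	CG	CB	CA	1.382	119.95	chi2
TYR	CD2	CG	CB	CA	1.383	119.94	chi2+179.69
TYR	CE1	CD1	CG	CB	1.381	120.07	-179.98
TYR	CE2	CD2	CG	CB	1.381	120.02	179.77
TYR	CZ	CE1	CD1	CG	1.387	119.98	-0.10
TYR	OH	CZ	CE1	CD1	1.358	120.13	-179.97
VAL	CB	CA	N	C	1.529	109.45	-120.00
VAL	CG1	CB	CA	N	1.530	109.51	chi1
VAL	CG2	CB	CA	N	1.529	109.49	chi1+120.03
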