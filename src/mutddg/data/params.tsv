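res	atom	charge	eps	rmin_half	pb_radius
ALA	N	-0.1600	0.170	1.85	1.85
ALA	CA	0.1600	0.080	2.00	2.00
ALA	C	0.5100	0.080	2.00	2.00
ALA	O	-0.5100	0.120	1.70	1.70
ALA	CB	0.0000	0.080	2.00	2.00
ARG	N	-0.1600	0.170	1.85	1.85
ARG	CA	0.1600	0.080	2.00	2.00
ARG	C	0.5100	0.080	2.00	2.00
ARG	O	-0.5100	0.120	1.70	1.70
ARG	CB	0.0000	0.080	2.00	2.00
ARG	CG	0.0000	0.080	2.00	2.00
ARG	CD	0.0000	0.080	2.00	2.00
ARG	NE	-0.1000	0.170	1.85	1.85
ARG	CZ	0.6400	0.080	2.00	2.00
ARG	NH1	0.2300	0.170	1.85	1.85
ARG	NH2	0.2300	0.170	1.85	1.85
ASN	N	-0.1600	0.170	1.85	1.85
ASN	CA	0.1600	0.080	2.00	2.00
ASN	C	0.5100	0.080	2.00	2.00
ASN	O	-0.5100	0.120	1.70	1.70
ASN	CB	-0.0200	0.080	2.00	2.00
ASN	CG	0.5500	0.080	2.00	2.00
ASN	OD1	-0.5500	0.120	1.70	1.70
ASN	ND2	0.0200	0.170	1.85	1.85
ASP	N	-0.1600	0.170	1.85	1.85
ASP	CA	0.1600	0.080	2.00	2.00
ASP	C	0.5100	0.080	2.00	2.00
ASP	O	-0.5100	0.120	1.70	1.70
ASP	CB	-0.1000	0.080	2.00	2.00
ASP	CG	0.6200	0.080	2.00	2.00
ASP	OD1	-0.7600	0.120	1.70	1.70
ASP	OD2	-0.7600	0.120	1.70	1.70
CYS	N	-0.1600	0.170	1.85	1.85
CYS	CA	0.1600	0.080	2.00	2.00
CYS	C	0.5100	0.080	2.00	2.00
CYS	O	-0.5100	0.120	1.70	1.70
CYS	CB	0.0700	0.080	2.00	2.00
CYS	SG	-0.0700	0.450	2.00	2.00
GLN	N	-0.1600	0.170	1.85	1.85
GLN	CA	0.1600	0.080	2.00	2.00
GLN	C	0.5100	0.080	2.00	2.00
GLN	O	-0.5100	0.120	1.70	1.70
GLN	CB	0.0000	0.080	2.00	2.00
GLN	CG	-0.0200	0.080	2.00	2.00
GLN	CD	0.5500	0.080	2.00	2.00
GLN	OE1	-0.5500	0.120	1.70	1.70
GLN	NE2	0.0200	0.170	1.85	1.85
GLU	N	-0.1600	0.170	1.85	1.85
GLU	CA	0.1600	0.080	2.00	2.00
GLU	C	0.5100	0.080	2.00	2.00
GLU	O	-0.5100	0.120	1.70	1.70
GLU	CB	0.0000	0.080	2.00	2.00
GLU	CG	-0.1000	0.080	2.00	2.00
GLU	CD	0.6200	0.080	2.00	2.00
GLU	OE1	-0.7600	0.120	1.70	1.70
GLU	OE2	-0.7600	0.120	1.70	1.70
GLY	N	-0.1600	0.170	1.85	1.85
GLY	CA	0.1600	0.080	2.00	2.00
GLY	C	0.5100	0.080	2.00	2.00
GLY	O	-0.5100	0.120	1.70	1.70
HIS	N	-0.1600	0.170	1.85	1.85
HIS	CA	0.1600	0.080	2.00	2.00
HIS	C	0.5100	0.080	2.00	2.00
HIS	O	-0.5100	0.120	1.70	1.70
HIS	CB	0.0000	0.080	2.00	2.00
HIS	CG	0.0500	0.080	2.00	2.00
HIS	ND1	-0.2000	0.170	1.85	1.85
HIS	CD2	0.1000	0.080	2.00	2.00
HIS	CE1	0.2500	0.080	2.00	2.00
HIS	NE2	-0.2000	0.170	1.85	1.85
ILE	N	-0.1600	0.170	1.85	1.85
ILE	CA	0.1600	0.080	2.00	2.00
ILE	C	0.5100	0.080	2.00	2.00
ILE	O	-0.5100	0.120	1.70	1.70
ILE	CB	0.0000	0.080	2.00	2.00
ILE	CG1	0.0000	0.080	2.00	2.00
ILE	CG2	0.0000	0.080	2.00	2.00
ILE	CD1	0.0000	0.080	2.00	2.00
LEU	N	-0.1600	0.170	1.85	1.85
LEU	CA	0.1600	0.080	2.00	2.00
LEU	C	0.5100	0.080	2.00	2.00
LEU	O	-0.5100	0.120	1.70	1.70
LEU	CB	0.0000	0.080	2.00	2.00
LEU	CG	0.0000	0.080	2.00	2.00
LEU	CD1	0.0000	0.080	2.00	2.00
LEU	CD2	0.0000	0.080	2.00	2.00
LYS	N	-0.1600	0.170	1.85	1.85
LYS	CA	0.1600	0.080	2.00	2.00
LYS	C	0.5100	0.080	2.00	2.00
LYS	O	-0.5100	0.120	1.70	1.70
LYS	CB	0.0000	0.080	2.00	2.00
LYS	CG	0.0000	0.080	2.00	2.00
LYS	CD	0.0000	0.080	2.00	2.00
LYS	CE	0.3100	0.080	2.00	2.00
LYS	NZ	0.6900	0.170	1.85	1.85
MET	N	-0.1600	0.170	1.85	1.85
MET	CA	0.1600	0.080	2.00	2.00
MET	C	0.5100	0.080	2.00	2.00
MET	O	-0.5100	0.120	1.70	1.70
MET	CB	0.0000	0.080	2.00	2.00
MET	CG	0.0500	0.080	2.00	2.00
MET	SD	-0.0900	0.450	2.00	2.00
MET	CE	0.0400	0.080	2.00	2.00
PHE	N	-0.1600	0.170	1.85	1.85
PHE	CA	0.1600	0.080	2.00	2.00
PHE	C	0.5100	0.080	2.00	2.00
PHE	O	-0.5100	0.120	1.70	1.70
PHE	CB	0.0000	0.080	2.00	2.00
PHE	CG	0.0000	0.080	2.00	2.00
PHE	CD1	0.0000	0.080	2.00	2.00
PHE	CD2	0.0000	0.080	2.00	2.00
PHE	CE1	0.0000	0.080	2.00	2.00
PHE	CE2	0.0000	0.080	2.00	2.00
PHE	CZ	0.0000	0.080	2.00	2.00
PRO	N	-0.1600	0.170	1.85	1.85
PRO	CA	0.1600	0.080	2.00	2.00
PRO	C	0.5100	0.080	2.00	2.00
PRO	O	-0.5100	0.120	1.70	1.70
PRO	CB	0.0000	0.080	2.00	2.00
PRO	CG	0.0000	0.080	2.00	2.00
PRO	CD	0.0000	0.080	2.00	2.00
SER	N	-0.1600	0.170	1.85	1.85
SER	CA	0.1600	0.080	2.00	2.00
SER	C	0.5100	0.080	2.00	2.00
SER	O	-0.5100	0.120	1.70	1.70
SER	CB	0.2300	0.080	2.00	2.00
SER	OG	-0.2300	0.120	1.70	1.70
THR	N	-0.1600	0.170	1.85	1.85
THR	CA	0.1600	0.080	2.00	2.00
THR	C	0.5100	0.080	2.00	2.00
THR	O	-0.5100	0.120	1.70	1.70
THR	CB	0.2300	0.080	2.00	2.00
THR	OG1	-0.2300	0.120	1.70	1.70
THR	CG2	0.0000	0.080	2.00	2.00
TRP	N	-0.1600	0.170	1.85	1.85
TRP	CA	0.1600	0.080	2.00	2.00
TRP	C	0.5100	0.080	2.00	2.00
TRP	O	-0.5100	0.120	1.70	1.70
TRP	CB	0.0000	0.080	2.00	2.00
TRP	CG	0.0000	0.080	2.00	2.00
TRP	CD1	0.1100	0.080	2.00	2.00
TRP	CD2	0.0000	0.080	2.00	2.00
TRP	NE1	-0.2300	0.170	1.85	1.85
TRP	CE2	0.1200	0.080	2.00	2.00
TRP	CE3	0.0000	0.080	2.00	2.00
TRP	CZ2	0.0000	0.080	2.00	2.00
TRP	CZ3	0.0000	0.080	2.00	2.00
TRP	CH2	0.0000	0.080	2.00	2.00
TYR	N	-0.1600	0.170	1.85	1.85
TYR	CA	0.1600	0.080	2.00	2.00
TYR	C	0.5100	0.080	2.00	2.00
TYR	O	-0.5100	0.120	1.70	1.70
TYR	CB	0.0000	0.080	2.00	2.00
TYR	CG	0.0000	0.080	2.00	2.00
TYR	CD1	0.0000	0.080	2.00	2.00
TYR	CD2	0.0000	0.080	2.00	2.00
TYR	CE1	0.0600	0.080	2.00	2.00
TYR	CE2	0.0600	0.080	2.00	2.00
TYR	CZ	0.1100	0.080	2.00	2.00
TYR	OH	-0.2300	0.120	1.70	1.70
VAL	N	-0.1600	0.170	1.85	1.85
VAL	CA	0.1600	0.080	2.00	2.00
VAL	C	0.5100	0.080	2.00	2.00
VAL	O	-0.5100	0.120	1.70	1.70
VAL	CB	0.0000	0.080	2.00	2.00
VAL	CG1	0.0000	0.080	2.00	2.00
VAL	CG2	0.0000	0.080	2.00	2.00
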