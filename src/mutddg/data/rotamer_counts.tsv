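res	n_rotamers
ALA	1
ARG	81
ASN	6
ASP	6
CYS	3
GLN	18
GLU	18
GLY	1
HIS	6
ILE	9
LEU	9
LYS	81
MET	27
PHE	6
PRO	2
SER	3
THR	3
TRP	6
TYR	6
VAL	3
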