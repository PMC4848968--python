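res	max_sasa
ALA	119.452
ARG	264.156
ASN	172.519
ASP	169.404
CYS	150.590
GLN	193.912
GLU	191.460
GLY	93.220
HIS	209.007
ILE	185.372
LEU	182.563
LYS	218.955
MET	201.433
PHE	227.920
PRO	143.868
SER	134.918
THR	155.994
TRP	268.020
TYR	242.306
VAL	160.234
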