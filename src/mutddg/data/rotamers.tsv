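res	index	chi1	chi2	chi3	chi4
ARG	0	-60.00	-60.00	180.00	180.00
ARG	1	-60.00	180.00	180.00	180.00
ARG	2	-60.00	60.00	180.00	180.00
ARG	3	180.00	-60.00	180.00	180.00
ARG	4	180.00	180.00	180.00	180.00
ARG	5	180.00	60.00	180.00	180.00
ARG	6	60.00	-60.00	180.00	180.00
ARG	7	60.00	180.00	180.00	180.00
ARG	8	60.00	60.00	180.00	180.00
ASN	0	-60.00	-90.00		
ASN	1	-60.00	0.00		
ASN	2	-60.00	90.00		
ASN	3	180.00	-90.00		
ASN	4	180.00	0.00		
ASN	5	180.00	90.00		
ASN	6	60.00	-90.00		
ASN	7	60.00	0.00		
ASN	8	60.00	90.00		
ASP	0	-60.00	-30.00		
ASP	1	-60.00	30.00		
ASP	2	-60.00	90.00		
ASP	3	180.00	-30.00		
ASP	4	180.00	30.00		
ASP	5	180.00	90.00		
ASP	6	60.00	-30.00		
ASP	7	60.00	30.00		
ASP	8	60.00	90.00		
CYS	0	-60.00			
CYS	1	180.00			
CYS	2	60.00			
GLN	0	-60.00	-60.00	-90.00	
GLN	1	-60.00	-60.00	0.00	
GLN	2	-60.00	-60.00	90.00	
GLN	3	-60.00	180.00	-90.00	
GLN	4	-60.00	180.00	0.00	
GLN	5	-60.00	180.00	90.00	
GLN	6	-60.00	60.00	-90.00	
GLN	7	-60.00	60.00	0.00	
GLN	8	-60.00	60.00	90.00	
GLN	9	180.00	-60.00	-90.00	
GLN	10	180.00	-60.00	0.00	
GLN	11	180.00	-60.00	90.00	
GLN	12	180.00	180.00	-90.00	
GLN	13	180.00	180.00	0.00	
GLN	14	180.00	180.00	90.00	
GLN	15	180.00	60.00	-90.00	
GLN	16	180.00	60.00	0.00	
GLN	17	180.00	60.00	90.00	
GLN	18	60.00	-60.00	-90.00	
GLN	19	60.00	-60.00	0.00	
GLN	20	60.00	-60.00	90.00	
GLN	21	60.00	180.00	-90.00	
GLN	22	60.00	180.00	0.00	
GLN	23	60.00	180.00	90.00	
GLN	24	60.00	60.00	-90.00	
GLN	25	60.00	60.00	0.00	
GLN	26	60.00	60.00	90.00	
GLU	0	-60.00	-60.00	-30.00	
GLU	1	-60.00	-60.00	30.00	
GLU	2	-60.00	-60.00	90.00	
GLU	3	-60.00	180.00	-30.00	
GLU	4	-60.00	180.00	30.00	
GLU	5	-60.00	180.00	90.00	
GLU	6	-60.00	60.00	-30.00	
GLU	7	-60.00	60.00	30.00	
GLU	8	-60.00	60.00	90.00	
GLU	9	180.00	-60.00	-30.00	
GLU	10	180.00	-60.00	30.00	
GLU	11	180.00	-60.00	90.00	
GLU	12	180.00	180.00	-30.00	
GLU	13	180.00	180.00	30.00	
GLU	14	180.00	180.00	90.00	
GLU	15	180.00	60.00	-30.00	
GLU	16	180.00	60.00	30.00	
GLU	17	180.00	60.00	90.00	
GLU	18	60.00	-60.00	-30.00	
GLU	19	60.00	-60.00	30.00	
GLU	20	60.00	-60.00	90.00	
GLU	21	60.00	180.00	-30.00	
GLU	22	60.00	180.00	30.00	
GLU	23	60.00	180.00	90.00	
GLU	24	60.00	60.00	-30.00	
GLU	25	60.00	60.00	30.00	
GLU	26	60.00	60.00	90.00	
HIS	0	-60.00	-90.00		
HIS	1	-60.00	90.00		
HIS	2	180.00	-90.00		
HIS	3	180.00	90.00		
HIS	4	60.00	-90.00		
HIS	5	60.00	90.00		
ILE	0	-60.00	-60.00		
ILE	1	-60.00	180.00		
ILE	2	-60.00	60.00		
ILE	3	180.00	-60.00		
ILE	4	180.00	180.00		
ILE	5	180.00	60.00		
ILE	6	60.00	-60.00		
ILE	7	60.00	180.00		
ILE	8	60.00	60.00		
LEU	0	-60.00	-60.00		
LEU	1	-60.00	180.00		
LEU	2	-60.00	60.00		
LEU	3	180.00	-60.00		
LEU	4	180.00	180.00		
LEU	5	180.00	60.00		
LEU	6	60.00	-60.00		
LEU	7	60.00	180.00		
LEU	8	60.00	60.00		
LYS	0	-60.00	-60.00	180.00	180.00
LYS	1	-60.00	180.00	180.00	180.00
LYS	2	-60.00	60.00	180.00	180.00
LYS	3	180.00	-60.00	180.00	180.00
LYS	4	180.00	180.00	180.00	180.00
LYS	5	180.00	60.00	180.00	180.00
LYS	6	60.00	-60.00	180.00	180.00
LYS	7	60.00	180.00	180.00	180.00
LYS	8	60.00	60.00	180.00	180.00
MET	0	-60.00	-60.00	-60.00	
MET	1	-60.00	-60.00	180.00	
MET	2	-60.00	-60.00	60.00	
MET	3	-60.00	180.00	-60.00	
MET	4	-60.00	180.00	180.00	
MET	5	-60.00	180.00	60.00	
MET	6	-60.00	60.00	-60.00	
MET	7	-60.00	60.00	180.00	
MET	8	-60.00	60.00	60.00	
MET	9	180.00	-60.00	-60.00	
MET	10	180.00	-60.00	180.00	
MET	11	180.00	-60.00	60.00	
MET	12	180.00	180.00	-60.00	
MET	13	180.00	180.00	180.00	
MET	14	180.00	180.00	60.00	
MET	15	180.00	60.00	-60.00	
MET	16	180.00	60.00	180.00	
MET	17	180.00	60.00	60.00	
MET	18	60.00	-60.00	-60.00	
MET	19	60.00	-60.00	180.00	
MET	20	60.00	-60.00	60.00	
MET	21	60.00	180.00	-60.00	
MET	22	60.00	180.00	180.00	
MET	23	60.00	180.00	60.00	
MET	24	60.00	60.00	-60.00	
MET	25	60.00	60.00	180.00	
MET	26	60.00	60.00	60.00	
PHE	0	-60.00	90.00		
PHE	1	-60.00	60.00		
PHE	2	-60.00	-60.00		
PHE	3	180.00	90.00		
PHE	4	180.00	60.00		
PHE	5	180.00	-60.00		
PHE	6	60.00	90.00		
PHE	7	60.00	60.00		
PHE	8	60.00	-60.00		
PRO	0	-23.80	0.03		
SER	0	-60.00			
SER	1	180.00			
SER	2	60.00			
THR	0	-60.00			
THR	1	180.00			
THR	2	60.00			
TRP	0	-60.00	-90.00		
TRP	1	-60.00	90.00		
TRP	2	-60.00	120.00		
TRP	3	180.00	-90.00		
TRP	4	180.00	90.00		
TRP	5	180.00	120.00		
TRP	6	60.00	-90.00		
TRP	7	60.00	90.00		
TRP	8	60.00	120.00		
TYR	0	-60.00	90.00		
TYR	1	-60.00	60.00		
TYR	2	-60.00	-60.00		
TYR	3	180.00	90.00		
TYR	4	180.00	60.00		
TYR	5	180.00	-60.00		
TYR	6	60.00	90.00		
TYR	7	60.00	60.00		
TYR	8	60.00	-60.00		
VAL	0	-60.00			
VAL	1	180.00			
VAL	2	60.00			
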