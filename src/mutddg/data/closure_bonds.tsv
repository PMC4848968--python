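res	atom1	atom2
PRO	CD	N
HIS	NE2	CD2
PHE	CZ	CE2
TYR	CZ	CE2
TRP	CE2	CD2
TRP	CH2	CZ3
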