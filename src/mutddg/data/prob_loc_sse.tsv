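kind	code	cases	p	pprime
loc	B-B	102	0.74	0.70
loc	B-PE	132	0.78	0.76
loc	E-E	457	0.31	0.29
loc	E-PE	130	0.56	0.55
loc	PE-PE	441	0.65	0.65
sse	BB	14	0.26	0.27
sse	CC	182	0.47	0.45
sse	CH	6	0.81	0.65
sse	CS	8	0.59	0.61
sse	CT	6	0.15	0.16
sse	HH	378	0.55	0.53
sse	HS	1	0.50	0.50
sse	HT	2	0.50	0.50
sse	SS	455	0.63	0.61
sse	ST	2	0.50	0.50
sse	TT	208	0.39	0.38
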