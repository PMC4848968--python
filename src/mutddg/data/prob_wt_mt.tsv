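aa	wt_cases	p_wt	pprime_wt	mt_cases	p_mt	pprime_mt
A	91	0.60	0.56	374	0.54	0.53
C	7	0.69	0.55	36	0.44	0.51
D	52	0.48	0.50	34	0.58	0.63
E	93	0.44	0.48	43	0.62	0.64
F	52	0.72	0.69	85	0.45	0.41
G	79	0.52	0.57	167	0.68	0.69
H	41	0.36	0.37	10	0.78	0.79
I	103	0.66	0.63	65	0.40	0.32
K	114	0.22	0.20	32	0.47	0.45
L	92	0.83	0.80	69	0.33	0.25
M	23	0.58	0.59	15	0.43	0.45
N	40	0.62	0.60	19	0.65	0.67
P	42	0.35	0.36	16	0.40	0.36
Q	25	0.25	0.30	41	0.26	0.30
R	37	0.51	0.49	20	0.62	0.53
S	40	0.30	0.21	55	0.60	0.53
T	86	0.50	0.46	39	0.74	0.70
V	141	0.61	0.59	107	0.58	0.52
W	23	0.81	0.86	17	0.44	0.45
Y	81	0.67	0.66	18	0.58	0.65
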