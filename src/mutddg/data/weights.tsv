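term	small	small_p	large	large_p	all	all_p
intercept	-7.44e-1	0.0	-2.27e0	0.0	-1.58e0	0.0
d_ie	9.28e-2	1.36e-2	NA	NA	NA	NA
dd_ee	5.93e-1	3.37e-7	8.54e-1	0.0	8.93e-1	0.0
dd_ve	7.51e-2	2.03e-4	1.63e-1	0.0	1.69e-1	0.0
dd_sp	4.53e-1	5.14e-8	6.32e-1	0.0	6.68e-1	0.0
d_s	NA	NA	4.07e-1	4.18e-2	4.85e-1	1.03e-3
d_hydr	NA	NA	NA	NA	-1.57e0	9.63e-3
d_ssum	-1.26e-1	1.99e-5	-6.55e-1	4.05e-4	-6.67e-1	2.24e-6
sas_mt	NA	NA	9.36e-5	1.10e-4	-5.46e1	2.88e-3
snsas_mt	NA	NA	-7.71e-1	6.84e-3	-2.78e1	4.77e-2
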