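trial	cu	ag	time	chh_sv	chh_dnmv	gsh	gpre
A	0.1	10	42	8.66	0.37	0.004591	0.87
A	0.1	10	42	8.66	0.37	0.00494	0.87
A	0.1	10	42	8.52	0.36	0.005324	0.87
B	0.1	60	49	8.64	0.37	0.004879	1.52
B	0.1	60	49	8.64	0.37	0.00512	1.52
B	0.1	60	49	8.79	0.37	0.005144	1.52
B	0.1	60	49	8.79	0.37	0.004353	1.52
B	0.1	60	49	8.79	0.56	0.004985	1.52
C	5	60	42	8.76	0.75	0.004768	0.71
C	5	60	42	8.79	0.56	0.005038	0.71
C	5	60	42	8.64	0.55	0.00412	0.71
D	5	0	49	8.64	0.55	0.005176	2.38
D	5	0	49	8.64	0.55	0.005264	2.38
D	5	0	49	8.76	0.75	0.005502	2.38
D	5	0	49	8.76	0.75	0.00604	2.38
D	5	0	49	8.76	0.75	0.005451	2.38
D	5	0	49	8.76	0.75	0.005293	2.38
D	5	0	49	8.76	0.75	0.005133	2.38
D	5	0	49	8.76	0.75	0.00552	2.38
D	5	0	49	8.76	0.75	0.004793	2.38
D	5	0	49	8.91	0.76	0.005358	2.38
E	5	10	35	8.63	0.73	0.004881	1.17
E	5	10	35	8.63	0.73	0.004362	1.17
E	5	10	35	8.48	0.72	0.004652	1.17
E	5	10	35	8.48	0.72	0.005249	1.17
E	5	10	35	8.50	0.54	0.005302	1.17
F	10	10	49	8.48	0.54	0.005046	3.79
F	10	10	49	8.65	0.55	0.005121	3.79
F	10	10	49	8.65	0.55	0.005566	3.79
G	10	60	35	8.62	0.56	0.005394	4.24
G	10	60	35	8.49	0.55	0.005685	4.24
G	10	60	35	8.49	0.55	0.005823	4.24
G	10	60	35	8.65	0.55	0.005085	4.24
H	10	0	42	8.49	0.55	0.005692	6.06
H	10	0	42	8.49	0.55	0.005502	6.06
H	10	0	42	8.65	0.55	0.004594	6.06
H	10	0	42	8.65	0.55	0.005502	6.06
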