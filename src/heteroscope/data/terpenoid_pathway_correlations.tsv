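gene	symbol	r_observed	q_observed	r_mph	q_mph
BraA01g044250.3C	IPP2	-0.4225	0.0016	-0.3671	0.0069
BraA02g023510.3C	HMG1	-0.3538	0.0094	-0.3694	0.0065
BraA02g028120.3C	HMGS	-0.3386	0.0131	-0.5465	2.30e-05
BraA03g011760.3C		-0.353	0.0095	-0.3878	0.0041
BraA06g027360.3C	FLCY	-0.3564	0.0088	-0.5517	1.85e-05
BraA07g002120.3C		-0.3555	0.009	-0.4595	0.0005
BraA08g025620.3C	ICMEL1	-0.391	0.0038	-0.5731	7.30e-06
BraA09g014810.3C	ISPF	-0.3647	0.0073	-0.3582	0.0084
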