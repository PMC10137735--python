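gene	symbol	r_observed	q_observed	r_mph	q_mph
BraA01g015640.3C	RPL7AB	0.3184	0.0202	0.351	0.01
BraA02g038190.3C	RPP2C	0.3917	0.0037	0.378	0.0053
BraA03g010340.3C	RPL10AC	0.4304	0.0013	0.4291	0.0013
BraA03g020910.3C	RPL23A	0.318	0.0203	0.7465	1.39e-10
BraA03g047490.3C	RPL15A	0.3514	0.0099	0.3096	0.0241
BraA04g006490.3C	RPL24B	0.3209	0.0191	0.4076	0.0025
BraA04g014040.3C	RPS10B	0.3328	0.0149	0.4193	0.0018
BraA05g028570.3C	RPL30B	0.366	0.007	0.4511	0.0007
BraA06g029850.3C	RPL6	0.4174	0.0019	0.4623	0.0005
BraA06g032890.3C		0.3173	0.0206	0.4261	0.0015
BraA07g012190.3C	RPL17B	0.3825	0.0047	0.3783	0.0052
BraA07g018220.3C	RPL10AB	0.4172	0.0019	0.5375	3.32e-05
BraA07g022360.3C	RPS26B	0.3703	0.0063	0.4319	0.0012
BraA07g031310.3C	RPL17B	0.3695	0.0065	0.4108	0.0022
BraA08g004460.3C	RPL18	0.3652	0.0072	0.5671	9.55e-06
BraA09g019250.3C	ARP1	0.2793	0.0428	0.357	0.0087
BraA09g022110.3C	RPL32A	0.3953	0.0034	0.4913	0.0002
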