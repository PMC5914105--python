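instrument	column	f_uracil	f_uridine	f_adenine	f_guanosine
Agilent 1100	Phenomenex	0.674	1.193	0.501	1.281
Agilent 1100	Agilent	0.676	1.189	0.461	1.300
Agilent 1260	Phenomenex	0.685	1.200	0.444	1.32
Agilent 1260	Agilent	0.712	1.249	0.471	1.385
Waters 2695	Phenomenex	0.676	1.203	0.432	1.269
Waters 2695	Agilent	0.693	1.199	0.451	1.306
mean		0.686	1.206	0.460	1.310
rsd_percent		1.46	2.19	2.42	4.09
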