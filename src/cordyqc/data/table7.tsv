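temperature_c	f_uracil	f_uridine	f_adenine	f_guanosine
25	0.677	1.195	0.445	1.310
30	0.693	1.199	0.451	1.306
35	0.676	1.194	0.443	1.290
mean	0.682	1.196	0.446	1.302
rsd_percent	0.95	0.26	0.42	1.06
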