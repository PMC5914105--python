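flow_rate_ml_min	f_uracil	f_uridine	f_adenine	f_guanosine
0.9	0.674	1.189	0.443	1.300
1.0	0.693	1.199	0.451	1.306
1.1	0.676	1.193	0.443	1.306
mean	0.681	0.194	0.446	1.304
rsd_percent	1.04	0.50	0.46	0.35
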