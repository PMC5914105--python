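injection_volume_ul	f_uracil	f_uridine	f_adenine	f_guanosine
2	0.702	1.227	0.482	1.384
4	0.706	1.235	0.474	1.359
6	0.709	1.240	0.486	1.398
8	0.711	1.245	0.474	1.387
10	0.712	1.249	0.471	1.385
12	0.719	1.267	0.480	1.410
15	0.717	1.254	0.478	1.398
mean	0.711	1.245	0.478	1.389
rsd_percent	0.83	1.05	1.09	1.15
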