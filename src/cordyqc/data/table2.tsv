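peak_number	analyte	slope	intercept	r_squared	range_low_ug_ml	range_high_ug_ml	lod_ug_ml	loq_ug_ml
1	uracil	41.219	5.2065	0.9997	0.338	33.8	0.005	0.025
2	uridine	23.568	-1.2283	1.0000	0.936	93.6	0.016	0.049
3	adenine	62.462	4.2509	0.9998	0.301	30.1	0.001	0.005
4	guanosine	22.077	-27.477	0.9992	1.208	120.8	0.038	0.151
5	adenosine	28.112	2.0196	1.0000	0.936	93.6	0.024	0.073
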