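alpha	b0	b1	b2
0.25	0.675	-0.245	-0.105
0.10	1.281	0.250	-0.305
0.05	1.645	0.678	-0.362
0.025	1.960	1.149	-0.391
0.01	2.326	1.822	-0.396
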