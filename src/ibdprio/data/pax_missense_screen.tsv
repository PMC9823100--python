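variant	hgvs_p	impact	polyphen2_hdiv	sift	provean
PAX6_index	p.P81S	missense	0.97	0.00	-2.985
PAX6_T2D-GENES_1	p.G13R	missense	1.0	0.0	-6.69
PAX6_T2D-GENES_2	p.P95L	missense	1.0	0.0	-8.21
PAX6_Ulm	p.D236E	missense	1.0	0.014	-3.15
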