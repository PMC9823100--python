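chrom	pos	ref	alt	gene	impact	hgvs_c	hgvs_p	af_overall	af_nfe	sift	polyphen2_hdiv	provean
11	31823225	G	A	PAX6	missense	c.C241T	p.P81S			0.00	0.97	-2.985
1	7897090	G	T	PER3	stop-gain	c.G3430T	p.E1144X	0.000012	0.0000264
16	22161180	G	A	VWA3A	synonymous	c.G3057A	p.A1019A	0.000021	0.000083
1	8557500	G	A	RERE	synonymous	c.C969T	p.N323N	0.000057	0.000085
4	147179909	C	T	SLC10A7	missense	c.G889A	p.A297T	0.004685	0.009372
5	132161522	G	A	SHROOM1	missense	c.C311T	p.P104L	0.00897	0.01279
6	139202137	T	C	ECT2L	missense	c.T1709C	p.V570A	0.004216	0.007084
11	32119904	G	A	RCN1	missense	c.G457A	p.A153T	0.006932	0.01048
1	10000000	A	G	DECOY1	non-coding			0.15	0.14
2	105000000	C	T	DECOY2	non-coding			0.32	0.30
4	150000000	G	A	DECOY3	non-coding			0.05	0.06
5	130000000	T	C	DECOY4	non-coding			0.01	0.012
6	140000000	A	C	DECOY5	non-coding			0.22	0.20
9	15000000	G	T	DECOY6	non-coding			0.45	0.44
20	20000000	C	G	DECOY7	non-coding			0.08	0.09
1	50000000	A	T	DECOY8	non-coding			0.0005	0.0006
3	60000000	G	C	DECOY9	non-coding			0.002	0.001
7	25000000	C	A	DECOY10	non-coding			0.0001	0.0002
11	60000000	T	G	DECOY11	non-coding			0.003	0.004
16	5000000	A	G	DECOY12	non-coding
20	40000000	G	A	DECOY13	non-coding			0.0008	0.0009
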