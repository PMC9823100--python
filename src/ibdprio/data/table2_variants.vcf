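##fileformat=VCFv4.2
##source=ibdprio-fixture
##contig=<ID=1,length=249000000>
##contig=<ID=2,length=243000000>
##contig=<ID=3,length=198000000>
##contig=<ID=4,length=191000000>
##contig=<ID=5,length=181000000>
##contig=<ID=6,length=171000000>
##contig=<ID=7,length=159000000>
##contig=<ID=9,length=141000000>
##contig=<ID=11,length=135000000>
##contig=<ID=16,length=90000000>
##contig=<ID=20,length=63000000>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM	POS	ID	REF	ALT	QUAL	FILTER	INFO	FORMAT	I	II	III	IV
1	7897090	.	G	T	.	PASS	.	GT	0/1	0/1	0/1	0/1
1	8557500	.	G	A	.	PASS	.	GT	0/1	0/1	0/1	0/1
1	10000000	.	A	G	.	PASS	.	GT	0/1	0/0	0/1	1/1
1	50000000	.	A	T	.	PASS	.	GT	0/1	0/1	0/0	0/0
2	105000000	.	C	T	.	PASS	.	GT	1/1	0/1	0/1	0/1
2	110000000	.	A	G	.	PASS	.	GT	0/1	0/1	0/1	0/1
3	60000000	.	G	C	.	PASS	.	GT	0/0	0/1	0/0	0/0
4	145000000	.	C	T	.	PASS	.	GT	0/1	0/1	0/1	0/1
4	147179909	.	C	T	.	PASS	.	GT	0/1	0/1	0/1	0/1
4	150000000	.	G	A	.	PASS	.	GT	0/1	1/1	0/1	0/1
5	125000000	.	G	A	.	PASS	.	GT	0/1	0/1	0/1	0/1
5	130000000	.	T	C	.	PASS	.	GT	0/0	0/1	0/1	0/1
5	132161522	.	G	A	.	PASS	.	GT	0/1	0/1	0/1	0/1
6	135000000	.	T	A	.	PASS	.	GT	0/1	0/1	0/1	0/1
6	139202137	.	T	C	.	PASS	.	GT	0/1	0/1	0/1	0/1
6	140000000	.	A	C	.	PASS	.	GT	0/1	0/1	1/1	0/1
7	25000000	.	C	A	.	PASS	.	GT	0/0	0/0	0/1	0/1
9	15000000	.	G	T	.	PASS	.	GT	0/1	0/1	0/1	1/1
9	20000000	.	A	C	.	PASS	.	GT	0/1	0/1	0/1	0/1
11	25000000	.	G	T	.	PASS	.	GT	0/1	0/1	0/1	0/1
11	31823225	.	G	A	.	PASS	.	GT	0/1	0/1	0/1	0/1
11	32119904	.	G	A	.	PASS	.	GT	0/1	0/1	0/1	0/1
11	60000000	.	T	G	.	PASS	.	GT	0/1	0/0	0/0	0/1
16	5000000	.	A	G	.	PASS	.	GT	0/0	0/1	0/1	0/0
16	15000000	.	C	G	.	PASS	.	GT	0/1	0/1	0/1	0/1
16	22161180	.	G	A	.	PASS	.	GT	0/1	0/1	0/1	0/1
20	20000000	.	C	G	.	PASS	.	GT	0/1	0/1	0/1	0/1
20	40000000	.	G	A	.	PASS	.	GT	1/1	0/1	0/1	0/1
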