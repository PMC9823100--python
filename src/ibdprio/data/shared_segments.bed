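# Synthetic stand-in for the nine autosomal regions shared IBD by all four
# sequenced individuals: constructed to cover the eight published coding
# variant positions and to match the published count (9), total span
# (194.8 Mb) and mean length (21.6 Mb). Coordinates are 0-based half-open.
1	2000000	32000000
2	100000000	118000000
4	140000000	160000000
5	120000000	145000000
6	130000000	152000000
9	10000000	25000000
11	20000000	48000000
16	12000000	29800000
20	10000000	29000000
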