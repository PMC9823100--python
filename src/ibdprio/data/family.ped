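FAM1	I	0	0	2	2
FAM1	II	0	0	1	2
FAM2	III	0	0	1	2
FAM2	IV	0	0	1	2
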