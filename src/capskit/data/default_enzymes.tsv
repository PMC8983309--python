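name	recognition	cut_top	cut_bottom	isoschizomers
BstV1I	GCAGC	13	17	BseXI;BbvI
Acc36I	ACCTGC	10	14	BveI;BspMI
BstHHI	GCGC	3	3	AspLEI;CfoI;Hin6I;HinP1I;HspAI
HinfI	GANTC	1	1
BstSFI	CTRYAG	1	1	BfmI;SfcI
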