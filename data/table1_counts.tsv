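SOURCE	POS	NEG
BPPV	13	29
sample_controls	1	49
ExAC	11	2739
NHLBI_EA	476	3054
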