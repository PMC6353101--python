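method	printed_per_sample	printed_per_batch
qpcr	5.82	563.09
barcoding	18.79	1319
morphological	13	1248
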