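method	step	min_hours	max_hours
qpcr	DNA Extraction Prep	1	1
qpcr	DNA Extraction Incubation	3	4
qpcr	Real-Time PCR Prep	1	1
qpcr	Real-Time PCR Run	0.5	0.5
qpcr	Analysis	0.5	0.5
barcoding	DNA Extraction Prep	1	1
barcoding	DNA Extraction Incubation	3	4
barcoding	PCR Prep	0.5	0.5
barcoding	PCR Run	2	2
barcoding	Gel Electrophoresis Prep	0.5	0.5
barcoding	Gel Electrophoresis Run	1	2
barcoding	PCR Purification	1	1
barcoding	Analysis	1	1
morphological	Labour	8	16
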