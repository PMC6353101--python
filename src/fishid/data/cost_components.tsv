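method	label	per_sample	per_batch
qpcr	DNA Extraction Kit	3.39	325.44
qpcr	Primers	0.0003	0.03
qpcr	Probes	0.02	1.92
qpcr	Hydrolysis Mix	1.40	134.40
qpcr	Microamp 96-well Plates	0.01	1.30
qpcr	Labour	1	100
barcoding	DNA Extraction Kit	3.39	325.44
barcoding	Primers	0.0009	0.08
barcoding	iQ MasterMix	2.81	269.76
barcoding	Agarose Gel and Loading Dye	3.04	40.07
barcoding	PCR Purification Kit	2.61	250.75
barcoding	Strip Tubes	0.47	5.64
barcoding	Sanger Sequencing	3.50	336
barcoding	Labour	1	100
morphological	Labour	13	1248
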