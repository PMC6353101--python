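species	probe_set	dye	forward	reverse	probe	forward_conc_nM	reverse_conc_nM	probe_conc_nM	annealing_temp_C	expected_amplicon_bp
Smallmouth Bass	1	FAM	TCTTTCCTTCTCCTGCTCGC	GGAGACACCCGCAAGATGAA	GCTGGAGCTGGCACTGGGTG	50	50	100	60	147
Spottail Shiner	1	VIC	CTATTATTAGCTTCTTCTGGGGTTG	GAGGTCTACTGATGCGCCC	GCAGGCAATCTTGCCCACGC	50	50	100	60	105
Round Whitefish	1	ABY	AATGTAATCGTCACGGCCCA	CGGGGGAATGCTATATCGGG	TGACTAATTCCCCTTATGATCGGAGCA	500	500	100	60	125
Brook Trout	1	JUN	CGGTACGGGGTGAACAGTTT	GGAAATGCCAGCTAAATGTAGGG	CTCGCCCACGCAGGAGCTTC	400	400	200	60	103
Lake Whitefish	2	FAM	TCTCCCTCCACTTAGCTGGT	GCCCAGACAAAAAGAGGGGT	TTCCTCTATCTTGGGGGCCGTT	200	400	200	60	118
Deepwater Sculpin	2	VIC	CTTAGCCTCTTCGGGGGTTG	TGCTCCGAGGATCGAAGAGA	CCACGCGGGAGCCTCTGTTG	100	100	100	60	148
Rainbow Smelt	2	ABY	CGATTATGATCGGCGGGTTTG	ATGCGAGGGAAGGCCATATC	CCCCCTTATGATTGGGGCCCCA	400	400	200	60	76
Yellow Perch	2	JUN	GATCGGTGCCCCTGACATAG	TCCCAGCAAGAGGGGGATAA	AAGCCGGAGCTGGTACCGGA	200	400	200	60	146
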