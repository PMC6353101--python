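probe_set	assay_species	sample_species	n_samples	mean_cq	sem
1	Smallmouth Bass	Smallmouth Bass	1	28.71	0.058
1	Smallmouth Bass	Spottail Shiner	1
1	Smallmouth Bass	Round Whitefish	1
1	Smallmouth Bass	Brook Trout	1
1	Spottail Shiner	Spottail Shiner	1	21.37	0.15
1	Spottail Shiner	Smallmouth Bass	1
1	Spottail Shiner	Round Whitefish	1
1	Spottail Shiner	Brook Trout	1
1	Round Whitefish	Round Whitefish	1	25.23	0.22
1	Round Whitefish	Spottail Shiner	1
1	Round Whitefish	Smallmouth Bass	1
1	Round Whitefish	Brook Trout	1
1	Brook Trout	Brook Trout	1	23.44	0.11
1	Brook Trout	Spottail Shiner	1
1	Brook Trout	Round Whitefish	1
1	Brook Trout	Smallmouth Bass	1
2	Lake Whitefish	Lake Whitefish	1	21.48	0.065
2	Lake Whitefish	Deepwater Sculpin	1
2	Lake Whitefish	Rainbow Smelt	1
2	Lake Whitefish	Yellow Perch	1
2	Deepwater Sculpin	Deepwater Sculpin	1	21.37	0.027
2	Deepwater Sculpin	Lake Whitefish	1
2	Deepwater Sculpin	Rainbow Smelt	1
2	Deepwater Sculpin	Yellow Perch	1
2	Rainbow Smelt	Rainbow Smelt	1	21.48	0.048
2	Rainbow Smelt	Deepwater Sculpin	1
2	Rainbow Smelt	Lake Whitefish	1
2	Rainbow Smelt	Yellow Perch	1
2	Yellow Perch	Yellow Perch	1	23.44	0.039
2	Yellow Perch	Deepwater Sculpin	1
2	Yellow Perch	Rainbow Smelt	1
2	Yellow Perch	Lake Whitefish	1
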