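probe_set	assay_species	sample_species	n_samples	mean_cq	sem
1	Smallmouth Bass	Smallmouth Bass	10	23.79	0.69
1	Smallmouth Bass	Spottail Shiner	10
1	Smallmouth Bass	Round Whitefish	10
1	Smallmouth Bass	Brook Trout	4
1	Smallmouth Bass	Lake Whitefish	5
1	Smallmouth Bass	Deepwater Sculpin	5
1	Smallmouth Bass	Rainbow Smelt	14
1	Smallmouth Bass	Yellow Perch	10
1	Smallmouth Bass	Largemouth Bass	6
1	Spottail Shiner	Spottail Shiner	10	22.61	1.14
1	Spottail Shiner	Smallmouth Bass	10
1	Spottail Shiner	Round Whitefish	10
1	Spottail Shiner	Brook Trout	4
1	Spottail Shiner	Lake Whitefish	5
1	Spottail Shiner	Deepwater Sculpin	5
1	Spottail Shiner	Rainbow Smelt	14
1	Spottail Shiner	Yellow Perch	10
1	Spottail Shiner	Bigmouth Shiner	2
1	Spottail Shiner	Carmine Shiner	3
1	Spottail Shiner	Rosyface Shiner	2
1	Spottail Shiner	Weed Shiner	3
1	Round Whitefish	Round Whitefish	10	19.79	1.18
1	Round Whitefish	Smallmouth Bass	10
1	Round Whitefish	Spottail Shiner	10
1	Round Whitefish	Brook Trout	4
1	Round Whitefish	Lake Whitefish	5
1	Round Whitefish	Deepwater Sculpin	5
1	Round Whitefish	Rainbow Smelt	14
1	Round Whitefish	Yellow Perch	10	36.35	0.46
1	Round Whitefish	Pygmy Whitefish	3	35.5	0.43
1	Brook Trout	Brook Trout	4	16.74	0.65
1	Brook Trout	Smallmouth Bass	10
1	Brook Trout	Spottail Shiner	10
1	Brook Trout	Round Whitefish	10
1	Brook Trout	Lake Whitefish	5	32.61	0.15
1	Brook Trout	Deepwater Sculpin	5
1	Brook Trout	Rainbow Smelt	14
1	Brook Trout	Yellow Perch	10
1	Brook Trout	Lake Trout	2	39.64	1.36
1	Brook Trout	Arctic Char	2	38.49	0.19
1	Brook Trout	Bull Trout	2	36.74	0.52
1	Brook Trout	Dolly Varden	2	39.36	0.25
2	Lake Whitefish	Lake Whitefish	5	16.21	0.35
2	Lake Whitefish	Deepwater Sculpin	5
2	Lake Whitefish	Rainbow Smelt	14
2	Lake Whitefish	Yellow Perch	10
2	Lake Whitefish	Smallmouth Bass	10	37.66	0.21
2	Lake Whitefish	Round Whitefish	10	37.71	0.11
2	Lake Whitefish	Spottail Shiner	10
2	Lake Whitefish	Brook Trout	4
2	Lake Whitefish	Cisco	2
2	Lake Whitefish	Bloater	1
2	Lake Whitefish	Kiyi	1
2	Deepwater Sculpin	Deepwater Sculpin	5	18.13	0.43
2	Deepwater Sculpin	Lake Whitefish	5
2	Deepwater Sculpin	Rainbow Smelt	14
2	Deepwater Sculpin	Yellow Perch	10
2	Deepwater Sculpin	Smallmouth Bass	10
2	Deepwater Sculpin	Round Whitefish	10
2	Deepwater Sculpin	Spottail Shiner	10
2	Deepwater Sculpin	Brook Trout	4
2	Rainbow Smelt	Rainbow Smelt	14	18.83	0.38
2	Rainbow Smelt	Lake Whitefish	5
2	Rainbow Smelt	Deepwater Sculpin	5
2	Rainbow Smelt	Yellow Perch	10
2	Rainbow Smelt	Smallmouth Bass	10
2	Rainbow Smelt	Round Whitefish	10	35.83	0.49
2	Rainbow Smelt	Spottail Shiner	10
2	Rainbow Smelt	Brook Trout	4	32.66	0.039
2	Yellow Perch	Yellow Perch	10	19.12	0.37
2	Yellow Perch	Lake Whitefish	5
2	Yellow Perch	Deepwater Sculpin	5
2	Yellow Perch	Rainbow Smelt	14
2	Yellow Perch	Smallmouth Bass	10
2	Yellow Perch	Round Whitefish	10	36.36	0.46
2	Yellow Perch	Spottail Shiner	10	35.36	0.91
2	Yellow Perch	Brook Trout	4
2	Yellow Perch	Log Perch	3
2	Yellow Perch	Blackside Darter	2	39.04	1.96
2	Yellow Perch	River Darter	2
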