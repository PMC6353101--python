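probe_set	species	n_samples	role
1	Smallmouth Bass	10	target
1	Spottail Shiner	10	target
1	Round Whitefish	11	target
1	Brook Trout	4	target
1	Largemouth Bass	6	control
1	Pygmy Whitefish	3	control
1	Weed Shiner	3	control
1	Carmine Shiner	3	control
1	Rosyface Shiner	2	control
1	Bigmouth Shiner	2	control
1	Mimic Shiner	1	control
1	Silver Shiner	1	control
1	Sand Shiner	1	control
1	Blackchin Shiner	1	control
1	Pugnose Shiner	1	control
1	River Shiner	1	control
1	Arctic Char	2	control
1	Bull Trout	2	control
1	Lake Trout	2	control
1	Dolly Varden	2	control
2	Lake Whitefish	5	target
2	Deepwater Sculpin	5	target
2	Rainbow Smelt	14	target
2	Yellow Perch	10	target
2	Cisco	2	control
2	Bloater	1	control
2	Kiyi	1	control
2	Blackfin Cisco	1	control
2	Fourhorn Sculpin	1	control
2	Log Perch	3	control
2	Blackside Darter	2	control
2	River Darter	2	control
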