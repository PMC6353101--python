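target_species	con_species	in_great_lakes	matches	compared	percent	negative_control
Lake Whitefish	Cisco	Y	638	652	98	Y
Lake Whitefish	Bloater	Y	638	652	98	Y
Lake Whitefish	Kiyi	Y	636	652	98	Y
Lake Whitefish	Blackfin Cisco	Y	634	652	97	N
Lake Whitefish	Shortjaw Cisco	Y	636	652	98	N
Lake Whitefish	Arctic Cisco	N	639	652	98	N
Lake Whitefish	Atlantic Whitefish	N	632	652	97	N
Lake Whitefish	Bering Cisco	N	637	652	98	N
Lake Whitefish	Broad Whitefish	N	645	652	99	N
Lake Whitefish	Humpback Whitefish	N	645	648	99	N
Lake Whitefish	Sardine Cisco	N	640	652	98	N
Smallmouth Bass	Largemouth Bass	Y	600	652	92	Y
Deepwater Sculpin	Fourhorn Sculpin	N	649	652	99	N
Spottail Shiner	Pugnose Shiner	Y	586	648	90	Y
Spottail Shiner	Emerald Shiner	Y	590	651	91	N
Spottail Shiner	Bridle Shiner	Y	579	651	89	N
Spottail Shiner	Ghost Shiner	Y	594	651	91	N
Spottail Shiner	Blackchin Shiner	Y	585	648	90	Y
Spottail Shiner	Blacknose Shiner	Y	593	651	91	N
Spottail Shiner	Silver Shiner	Y	590	651	91	Y
Spottail Shiner	Rosyface Shiner	Y	585	651	90	Y
Spottail Shiner	Sand Shiner	Y	571	645	89	Y
Spottail Shiner	Weed Shiner	Y	570	651	88	Y
Spottail Shiner	Mimic Shiner	Y	590	651	91	Y
Spottail Shiner	Bigmouth Shiner	N	586	651	90	Y
Spottail Shiner	River Shiner	N	579	642	90	Y
Spottail Shiner	Carmine Shiner	N	592	651	91	Y
Rainbow Smelt	Pacific Rainbow Smelt	N	597	648	92	N
Yellow Perch	Log Perch	Y	643	652	83	N
Yellow Perch	Channel Darter	Y	557	652	85	Y
Yellow Perch	Blackside Darter	Y	553	653	85	Y
Yellow Perch	River Darter	Y	551	654	84	N
Round Whitefish	Pygmy Whitefish	Y	583	651	90	Y
Round Whitefish	Mountain Whitefish	N	624	651	96	N
Brook Trout	Bull Trout	Y	611	652	94	Y
Brook Trout	Lake Trout	Y	613	652	94	Y
Brook Trout	Arctic Char	N	616	652	94	Y
Brook Trout	Dolly Varden	N	617	652	95	Y
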