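well	role	dose	time_min	fluorescence
A1	sample	0.02	0	160
A1	sample	0.02	15	1180
A1	sample	0.02	30	1420
A1	sample	0.02	45	1450
A2	sample	0.02	0	150
A2	sample	0.02	15	1260
A2	sample	0.02	30	1480
A2	sample	0.02	45	1490
B1	sample	0.01	0	155
B1	sample	0.01	15	740
B1	sample	0.01	30	1080
B1	sample	0.01	45	1150
C1	sample	0.005	0	150
C1	sample	0.005	15	420
C1	sample	0.005	30	650
C1	sample	0.005	45	760
D1	control	0	0	150
D1	control	0	15	155
D1	control	0	30	150
D1	control	0	45	152
E1	blank	0	0	50
E1	blank	0	15	50
E1	blank	0	30	50
E1	blank	0	45	50
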