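gene_symbol	T1	T2	T3	N1	N2	N3
ADAM9	620.0	540.0	700.0	210.0	180.0	230.0
ADAM10	410.0	380.0	450.0	190.0	220.0	200.0
CTSB	900.0	1100.0	950.0	640.0	700.0	610.0
CTSD	780.0	820.0	760.0	500.0	520.0	480.0
MMP2	150.0	170.0	140.0	160.0	150.0	170.0
PRSS1	90.0	110.0	100.0	95.0	105.0	100.0
HTRA1	60.0	70.0	65.0	60.0	75.0	62.0
CAPN1	300.0	320.0	310.0	280.0	300.0	290.0
CASP3	120.0	130.0	110.0	115.0	125.0	120.0
USP7	80.0	85.0	90.0	82.0	88.0	86.0
ACTB	5000.0	5200.0	4900.0	5100.0	5050.0	4950.0
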