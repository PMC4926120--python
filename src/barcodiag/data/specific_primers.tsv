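name	sequence	bp	tm	product
Tde25F20	ATGAGCAGGAATAGTTGGTA	20	51.6	450
Tde451R24	ATAGGTCGTATATTGATTACTGTG	24	51.7
Tbr63F23	TTCGAGCAGAATTAGGTAATCCC	23	55.8	354
Tbr394R23	TTCCTGCTAAATGTAATCTAAAG	23	50.7
Tma41F22	GGAACCTCTTTAAGATTATTAG	22	49.7	490
Tma508R23	TTGCTGTAATTACCACAGCTCAG	23	57.2
Tfr379F22	CGTAGATTTAGCAATTTTCAGG	22	53.3	170
Tfr526R23	GTGAAAGAAGTAGAAGAATAGCG	23	52.2
Tca33F26	GAATAGTAGGCACTTCATTAAGACTC	26	56.3	337
Tca346R24	CCATGTGCAATGTTTGATGAGAGG	24	57.9
Tco261F23	GGCTCCTGCCACCCTCATTAAGA	23	61.7	238
Tco474R25	GGTATTCGTTCAAATGATATTCCTG	25	55.7
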