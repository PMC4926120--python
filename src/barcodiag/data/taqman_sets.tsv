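name	sequence	bp	tm	product
TdeF	CGTACAGAACTAGGAAAC	18	58.1	116
TdeR	CCGATTATTATAGGTATTACTATG	24	57.8
TdeP	FAM-TCCTTAATCGGGAATGACCAAAT-BHQ	23	65
TbrF	GAGCAGTAGCAATTACAG	18	58.9	84
TbrR	TTCGGTCGGTTAATAATATAG	21	58.7
TbrP	FAM-TCACTTCCAGTGTTAGCCGGTG-BHQ	22	69.6
TmaF	TCCTGGTTCTCTAATTGG	18	59.3	138
TmaR	GCTCCTAGTATAAGTGGAA	19	59.1
TmaP	FAM-AATGTAATTGTCACAGCCCATGC-BHQ	23	67.1
TfrF	CGTAGATTTAGCAATTTTCAGG	22	61.7	169
TfrR	TGAAAGAAGTAGAAGAATAGCG	22	61.9
TfrP	FAM-AGCTGGTATCTCATCAATTCTTGGAGC-BHQ	27	69.8
TcaF	GATCCTCTGTTGATCTTG	18	58.1	183
TcaR	CAGGAAGAGATAAGAGAAG	19	57.5
TcaP	FAM-TCTGGGAGCAGTTAATTTCATTACAAC-BHQ	27	66.8
TcoF	CAGGATGAACTGTTTACC	18	58.7	151
TcoR	GTAGGTCGTATATTAATTACTG	22	57.3
ToP	FAM-ATCATCTAATATCGCTCACGGAGGAG-BHQ	26	68.6
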