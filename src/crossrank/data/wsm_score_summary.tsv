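wsm	score	count
WSM1	0.5	1722
WSM1	1	535
WSM1	1.5	40
WSM1	2	38
WSM1	2.5	102
WSM1	3	21
WSM2	0.5	1722
WSM2	1	535
WSM2	1.5	78
WSM2	2	102
WSM2	2.5	21
WSM3	0.5	1966
WSM3	1	314
WSM3	1.5	131
WSM3	2	41
WSM3	2.5	6
WSM4	0.5	1722
WSM4	1	338
WSM4	1.5	235
WSM4	2	137
WSM4	2.5	16
WSM4	3	10
WSM5	1	1966
WSM5	1.5	220
WSM5	2	137
WSM5	2.5	112
WSM5	3	15
WSM5	3.5	8
WSM6	0.5	244
WSM6	1	1745
WSM6	1.5	202
WSM6	2	222
WSM6	2.5	34
WSM6	3	11
WSM7	1	1966
WSM7	2	357
WSM7	2.5	89
WSM7	3	29
WSM7	3.5	17
WSM8	0.5	1966
WSM8	1	314
WSM8	1.5	17
WSM8	2	114
WSM8	2.5	41
WSM8	3	6
WSM9	1	1966
WSM9	2	314
WSM9	3	149
WSM9	4	29
WSM10	1	1966
WSM10	2	314
WSM10	2.5	132
WSM10	3	17
WSM10	3.5	29
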