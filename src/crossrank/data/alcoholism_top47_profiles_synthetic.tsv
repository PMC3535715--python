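gene_id	symbol	MuAc	MuPref	HuAlc	HuAddChip	HuLink	Ce	Dr	Cross	in_initial_list
6863	TAC1	1	0	1	1	0	0	0	1	1
3725	JUN	1	0	1	1	0	0	0	1	1
2560	GABRB1	1	0	1	1	0	0	0	1	1
2555	GABRA2	1	0	1	1	0	0	0	1	1
887	CCKBR	1	0	1	1	0	0	0	1	1
885	CCK	1	0	1	1	0	0	0	1	1
55858	TMEM165	1	1	1	0	0	0	0	1	1
7077	TIMP2	1	1	1	0	0	0	0	1	1
7054	TH	1	1	1	0	0	0	0	1	1
6696	SPP1	1	1	1	0	0	0	0	1	1
6538	SLC6A11	1	1	1	0	0	0	0	1	1
5814	PURB	1	1	1	0	0	0	0	1	1
5581	PRKCE	1	1	1	0	0	0	0	1	1
84152	PPP1R1B	1	1	1	0	0	0	0	1	1
5179	PENK	1	1	1	0	0	0	0	1	1
23024	PDZRN3	1	1	1	0	0	0	0	1	1
11333	PDAP1	1	1	1	0	0	0	0	1	1
5091	PC	1	1	1	0	0	0	0	1	1
5087	PBX1	1	1	1	0	0	0	0	1	1
23620	NTSR2	1	1	1	0	0	0	0	1	1
4915	NTRK2	1	1	1	0	0	0	0	1	1
8013	NR4A3	1	1	1	0	0	0	0	1	1
4852	NPY	1	1	1	0	0	0	0	1	1
4887	NPY2R	1	1	1	0	0	0	0	1	1
8777	MPDZ	1	1	1	0	0	0	0	1	1
1432	MAPK14	1	1	1	0	0	0	0	1	1
10905	MAN1A2	1	1	1	0	0	0	0	1	1
3912	LAMB1	1	1	1	0	0	0	0	1	1
2932	GSK3B	1	1	1	0	0	0	0	1	1
51704	GPRC5B	1	1	1	0	0	0	0	1	1
55970	GNG12	1	1	1	0	0	0	0	1	1
2629	GBA	1	1	1	0	0	0	0	1	1
2566	GABRG2	1	1	1	0	0	0	0	1	1
2563	GABRD	1	1	1	0	0	0	0	1	1
2561	GABRB2	1	1	1	0	0	0	0	1	1
2550	GABBR1	1	1	1	0	0	0	0	1	1
1112	FOXN3	1	1	1	0	0	0	0	1	1
2355	FOSL2	1	1	1	0	0	0	0	1	1
1979	EIF4EBP2	1	1	1	0	0	0	0	1	1
1655	DDX5	1	1	1	0	0	0	0	1	1
25932	CLIC4	1	1	1	0	0	0	0	1	1
1128	CHRM1	1	1	1	0	0	0	0	1	1
832	CAPZB	1	1	1	0	0	0	0	1	1
627	BDNF	1	1	1	0	0	0	0	1	1
10396	ATP8A1	1	1	1	0	0	0	0	1	1
440	ASNS	1	1	1	0	0	0	0	1	1
63874	ABHD4	1	1	1	0	0	0	0	1	1
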