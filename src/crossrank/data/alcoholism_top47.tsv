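symbol	gene_id	score
TAC1	6863	2.5
JUN	3725	2.5
GABRB1	2560	2.5
GABRA2	2555	2.5
CCKBR	887	2.5
CCK	885	2.5
TMEM165	55858	2
TIMP2	7077	2
TH	7054	2
SPP1	6696	2
SLC6A11	6538	2
PURB	5814	2
PRKCE	5581	2
PPP1R1B	84152	2
PENK	5179	2
PDZRN3	23024	2
PDAP1	11333	2
PC	5091	2
PBX1	5087	2
NTSR2	23620	2
NTRK2	4915	2
NR4A3	8013	2
NPY	4852	2
NPY2R	4887	2
MPDZ	8777	2
MAPK14	1432	2
MAN1A2	10905	2
LAMB1	3912	2
GSK3B	2932	2
GPRC5B	51704	2
GNG12	55970	2
GBA	2629	2
GABRG2	2566	2
GABRD	2563	2
GABRB2	2561	2
GABBR1	2550	2
FOXN3	1112	2
FOSL2	2355	2
EIF4EBP2	1979	2
DDX5	1655	2
CLIC4	25932	2
CHRM1	1128	2
CAPZB	832	2
BDNF	627	2
ATP8A1	10396	2
ASNS	440	2
ABHD4	63874	2
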