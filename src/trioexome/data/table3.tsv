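gene	trio_id	chrom	pos	impact	aa_change	maf_esp	maf_1kg	rsid	novel
AKD1	#08	6	109894726	Missense	E755K	NR	NR	NR	Yes
ANAPC7	#21	12	110819574	Missense	R108H	NR	NR	NR	Yes
CHRM1	#41	11	62678572	Missense, initiator codon	M1V	NR	NR	NR	Yes
FOXN3	#30	14	89656737	Nonsense	Q119X	NR	NR	NR	Yes
GTF2H4	#35	6	30880156	Missense	R337Q	0.010308	0.01	rs3218820	No
ITPR2	#42	12	26808680	Missense	F850L	NR	NR	NR	Yes
LIMD1	#02	3	45637047	Missense	P226S	NR	NR	NR	Yes
METTL22	#30	16	8738455	Missense	A295V	NR	NR	NR	Yes
MLL3	#02	7	151849993	Missense	R234Q	NR	NR	NR	Yes
NLRC5	#43	16	57073761	Missense, splice site	R256M	NR	NR	NR	Yes
PLA2G4C	#24	19	48607867	Missense	A79S	NR	NR	rs13895674	No
PSMB7	#08	9	127119118	Missense	I216T	NR	NR	NR	Yes
RINL	#10	19	39359972	Missense	R404Q	NR	NR	NR	Yes
SND1	#24	7	127341354	Missense	S179L	NR	NR	rs24667910	No
STK36	#14	2	219538460	Missense	M12R	NR	NR	NR	Yes
SV2A	#20	1	149885128	Missense	E89K	NR	NR	NR	Yes
TRRAP	#35	7	98553842	Missense	S1977N	NR	NR	NR	Yes
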