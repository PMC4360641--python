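trio_id	sex	diagnosis	onset_age	n_homozygous	n_comp_het_genes	n_de_novo
#01	Male	ALS	44	0	0	0
#02	Female	ALS	49	0	0	2
#03	Female	ALS	35	0	0	0
#04	Female	ALS	26	0	0	0
#05	Female	ALS	50	0	1	0
#06	Male	ALS	36	0	0	0
#07	Male	ALS	36	0	0	0
#08	Female	PMA	51	0	0	2
#09	Male	ALS	53	0	0	0
#10	Male	ALS	44	0	0	1
#11	Female	ALS	53	0	1	0
#12	Female	PBP	58	1	0	0
#13	Male	ALS	53	1	0	0
#14	Male	ALS	27	0	2	1
#15	Male	ALS	35	0	1	0
#16	Male	FTDMND	58	0	1	0
#17	Male	ALS	51	0	0	0
#18	Female	ALS	47	0	0	0
#19	Male	ALS	53	0	1	0
#20	Male	ALS	56	4	0	1
#21	Male	ALS	45	0	0	1
#22	Male	ALS	46	1	0	0
#23	Male	ALS	44	0	1	0
#24	Male	ALS	36	0	2	2
#25	Female	ALS	42	0	0	0
#26	Male	ALS	41	0	1	0
#27	Male	ALS	47	0	0	0
#28	Male	PMA	55	0	0	0
#29	Female	PBP	55	0	0	0
#30	Male	ALS	50	1	0	2
#31	Female	ALS	53	0	0	0
#32	Male	ALS	57	0	0	0
#33	Male	ALS	42	0	0	0
#34	Male	ALS	48	0	0	0
#35	Male	ALS	46	0	0	2
#36	Male	ALS	59	0	1	0
#37	Male	ALS	28	0	0	0
#38	Female	ALS	45	0	0	0
#39	Female	ALS	53	1	0	0
#40	Female	ALS	63	0	0	0
#41	Male	ALS	37	0	1	1
#42	Male	ALS	30	0	1	1
#43	Female	PLS	45	0	0	1
#44	Male	ALS	46	0	0	0
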