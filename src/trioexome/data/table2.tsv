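gene	trio_id	chrom	pos	inheritance	impact	aa_change	maf_esp	maf_1kg	rsid
ABCA2	#24	9	139908464	Cpd Het	Missense	V1422F	0.008303	0.01	rs147917446
ABCA2	#24	9	139916347	Cpd Het	Missense	M224K	NR	NR	NR
ATP8B3	#16	19	1788909	Cpd Het	Missense	G1019D	0.003602	0	rs202137046
ATP8B3	#16	19	1796751	Cpd Het	Missense	C524Y	NR	NR	NR
CACNA1H	#14	16	1265267	Cpd Het	Missense	V1683M	NR	NR	NR
CACNA1H	#14	16	1265315	Cpd Het	Missense	A1699T	0.006668	0.0041	rs148651456
CNGA4	#24	11	6261613	Cpd Het	Missense	G197R	NR	NR	NR
CNGA4	#24	11	6261718	Cpd Het	Missense	V232M	NR	NR	NR
DENND2C	#20	1	115130508	Homozygous	Missense	Y833H; Y776H	0.004075	0.0023	rs61753528
DNAH10	#23	12	124323006	Cpd Het	Missense	M1518V	0.009286	0.0027	rs145483216
DNAH10	#23	12	124409693	Cpd Het	Missense	R3837C	0.002361	0.0027	rs144421774
DNAH2	#41	17	7727209	Cpd Het	Missense	R3757H	NR	NR	NR
DNAH2	#41	17	7734055	Cpd Het	Missense	G4003V	NR	NR	NR
DNAH9	#26	17	11775004	Cpd Het	Missense	L1963F	NR	NR	NR
DNAH9	#26	17	11840674	Cpd Het	Missense	I2671M	0.001307	NR	rs143953217
EIF4E1B	#20	5	176072210	Homozygous	Missense	R147H	0.003643	0.0023	rs115365515
GORASP1	#19	3	39140352	Cpd Het	Missense	D162Y	0.00692	0.01	rs13886448
GORASP1	#19	3	39142562	Cpd Het	Missense	A127V	0.004306	0.0037	rs61743223
GTF3C2	#20	2	27558834	Homozygous	Missense	L473V	0.002537	0.0005	rs148867164
HENMT1	#13	1	109193733	Homozygous	Missense	E166A	0.000461	0.0009	rs144705350
KIAA1755	#12	20	36848055	Homozygous	Missense	R845C	0.000384	NR	rs144671254
LBP	#14	20	36978016	Cpd Het	Missense	G64R	NR	NR	NR
LBP	#14	20	36979309	Cpd Het	Missense	V112D	0.000538	0.0005	rs138570528
MYO3B	#42	2	171356232	Cpd Het	Missense	Q1067R	0.000248	0.0005	rs200292179
MYO3B	#42	2	171400401	Cpd Het	Splice site	None	NR	NR	NR
RAB25	#20	1	156035717	Homozygous	Missense	E20G	0.005891	0.01	rs61751627
SERPINA10	#15	14	94750486	Cpd Het	Missense	Q384R	0.008304	0.0037	rs2232710
SERPINA10	#15	14	94756669	Cpd Het	Nonsense	R88X	0.005305	0.0032	rs2232698
SPTB	#11	14	65253667	Cpd Het	Missense	A1006T	0.001153	NR	rs151112486
SPTB	#11	14	65267517	Cpd Het	Missense	S278F	NR	NR	NR
TAF1L	#39	9	32631781	Homozygous	Missense	P1266R	0.002076	NR	rs140558556
TF	#30	3	133496032	Homozygous	Missense	G671E	0.003691	0.0032	rs121918677
THSD7B	#22	2	138373831	Homozygous	Missense	Q1141H	0.004745	0.0009	rs150657202
USH2A	#05	1	215844468	Cpd Het	Missense	P4660L	NR	NR	NR
USH2A	#05	1	216420214	Cpd Het	Missense	S841Y	0.005305	0.0027	rs111033282
WDR6	#36	3	49049385	Cpd Het	Missense	L140V	NR	NR	NR
WDR6	#36	3	49050499	Cpd Het	Missense	R460H	0.000846	0.0009	rs142520902
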