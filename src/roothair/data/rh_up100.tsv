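gene	annotation	rpkm_rh	rpkm_nrh	log2fc
AT2G24980	Proline-rich extensin-like family protein	282.55	0.145177	-10.9265
AT5G06630	proline-rich extensin-like family protein	350.094	0.263724	-10.3745
AT1G12560	ATEXP7, expansin A7	390.921	0.365196	-10.064
AT4G40090	AGP3, arabinogalactan protein 3	1002.28	1.07251	-9.86808
AT3G62680	ATPRP3, PRP3, proline-rich protein 3	419.939	0.453138	-9.85601
AT5G04960	Plant invertase/pectin methylesterase inhibitor	179.825	0.201765	-9.7997
AT3G09925	Pollen Ole e 1 allergen and extensin family protein	685.787	0.79408	-9.75426
AT4G25820	ATXTH14	758.459	0.933845	-9.66567
AT5G06640	Proline-rich extensin-like family protein	300.574	0.375472	-9.6448
AT3G54590	ATHRGP1, HRGP1, hydroxyproline-rich glycoprotein	882.994	1.10396	-9.64358
AT5G67400	RHS19, root hair specific 19	456.332	0.570824	-9.64282
AT4G13390	Proline-rich extensin-like family protein	346.903	0.436798	-9.63335
AT4G02270	RHS13, root hair specific 13	828.721	1.12794	-9.52106
AT4G00680	ADF8, actin depolymerizing factor 8	479.401	0.676228	-9.46951
AT1G62980	ATEXP18, expansin A18	208.435	0.345746	-9.23567
AT5G57530	AtXTH12	125.269	0.209592	-9.22322
AT5G35190	Proline-rich extensin-like family protein	467.479	0.808864	-9.17479
AT2G29620	Unknown protein	35.8692	0.067347	-9.05692
AT1G30870	Peroxidase superfamily protein	413.75	0.811178	-8.99453
AT1G12040	LRX1, leucine-rich repeat/extensin 1	184.771	0.367391	-8.97421
AT5G05500	Pollen Ole e 1 allergen and extensin family protein	467.413	0.954079	-8.93637
AT5G11440	CID5, IPD1, CTC-interacting domain 5	141.179	0.300056	-8.87808
AT1G48930	AtGH9C1, GH9C1, glycosyl hydrolase 9C1	212.097	0.450867	-8.87781
AT1G54970	ATPRP1, PRP1, RHS7, proline-rich protein 1	197.916	0.420925	-8.87711
AT2G41970	Protein kinase superfamily protein	232.38	0.551853	-8.71799
AT2G47540	Pollen Ole e 1 allergen and extensin family protein	213.419	0.513428	-8.69931
AT5G22410	RHS18, root hair specific 18	106.322	0.292415	-8.50621
AT2G47360	Unknown protein	62.0735	0.184463	-8.3945
AT2G30670	NAD(P)-binding Rossmann-fold superfamily protein	112.11	0.339629	-8.36674
AT3G10710	RHS12, root hair specific 12	57.5381	0.189001	-8.24998
AT2G45890	ATROPGEF4, RHS11	101.066	0.368687	-8.09869
AT5G49270	COBL9	80.4778	0.313345	-8.00469
AT5G22555	Unknown protein	196.529	0.860094	-7.83603
AT5G40860	Unknown protein	136.684	0.628081	-7.76568
AT3G54580	Proline-rich extensin-like family protein	1903.3	8.85952	-7.74706
AT4G09990	Protein of unknown function (DUF579)	189.187	0.903108	-7.7107
AT1G08090	ATNRT2.1, nitrate transporter 2:1	52.9332	0.266549	-7.63363
AT3G60330	AHA7, HA7, H(+)-ATPase 7	310.855	1.56648	-7.63257
AT2G33460	RIC1, ROP-interactive CRIB motif-containing protein 1	58.361	0.294145	-7.63233
AT4G26010	Peroxidase superfamily protein	461.842	2.38604	-7.59664
AT3G07070	Protein kinase superfamily protein	39.4694	0.207821	-7.56925
AT2G46860	AtPPa3, PPa3, pyrophosphorylase 3	111.429	0.593574	-7.55249
AT3G47040	Glycosyl hydrolase family protein	30.0456	0.168941	-7.47449
AT4G01110	Unknown protein	62.5961	0.387963	-7.33401
AT1G08990	PGSIP5, plant glycogenin-like starch initiation protein 5	62.0058	0.388489	-7.31838
AT5G51270	U-box domain-containing protein kinase family protein	31.5351	0.198535	-7.31142
AT5G58010	LRL3, LJRHL1-like 3	273.512	1.80494	-7.24351
AT3G49960	Peroxidase superfamily protein	159.373	1.06339	-7.22759
AT4G34580	COW1, SRH1	218.104	1.47609	-7.20709
AT3G51350	Eukaryotic aspartyl protease family protein	38.8901	0.274518	-7.14636
AT4G38390	RHS17, root hair specific 17	36.6331	0.260206	-7.13735
AT1G70460	RHS10, root hair specific 10	88.1011	0.641957	-7.10054
AT5G62310	IRE	64.0072	0.516494	-6.95334
AT4G29180	RHS16, root hair specific 16	55.3506	0.448309	-6.94796
AT5G17820	Peroxidase superfamily protein	1305.01	10.998	-6.89067
AT1G27740	RSL4, root hair defective 6-like 4	254.49	2.16234	-6.87888
AT1G09170	P-loop nucleoside triphosphate hydrolases	24.029	0.205787	-6.86748
AT4G30320	CAP superfamily protein	89.776	0.843779	-6.73332
AT5G49870	Mannose-binding lectin superfamily protein	31.8792	0.309214	-6.68786
AT1G51860	Leucine-rich repeat protein kinase family protein	8.1714	0.0812391	-6.65226
AT5G65160	tetratricopeptide repeat (TPR)-containing protein	74.2567	0.744421	-6.64026
AT4G02830	Unknown protein	34.9084	0.352575	-6.6295
AT5G01280	Proline-rich family protein (TAIR:AT3G09000.1)	52.2871	0.534523	-6.61206
AT5G61550	U-box domain-containing protein kinase family protein	35.9846	0.372456	-6.59417
AT4G25220	RHS15, root hair specific 15	24.1657	0.254417	-6.56962
AT2G17890	CPK16, calcium-dependent protein kinase 16	8.41945	0.0946467	-6.47503
AT2G45750	S-adenosyl-L-methionine-dependent methyltransferases	142.026	1.61829	-6.45554
AT4G25090	Riboflavin synthase-like superfamily protein	62.3366	0.714573	-6.44686
AT1G07795	Unknown protein	47.4163	0.554259	-6.41868
AT4G34380	Transducin/WD40 repeat-like superfamily protein	8.24351	0.0984524	-6.38769
AT5G25810	Tny, Integrase-type DNA-binding superfamily protein	21.4022	0.257057	-6.37953
AT2G37820	Cysteine/Histidine-rich C1 domain family protein	17.8879	0.221005	-6.33876
AT1G34760	GF14 OMICRON, GRF11, RHS5	50.7197	0.636707	-6.31577
AT4G25940	ENTH/ANTH/VHS superfamily protein	19.5987	0.246851	-6.31097
AT1G12550	D-isomer specific 2-hydroxyacid dehydrogenase	81.9584	1.03544	-6.30658
AT5G21080	Uncharacterized protein	30.2492	0.410728	-6.20257
AT5G65090	BST1, DER4, MRH3, DNAse I-like superfamily protein	41.273	0.593343	-6.12019
AT4G25110	AtMC2, MC2, metacaspase 2	25.4734	0.366441	-6.11927
AT3G18450	PLAC8 family protein	26.2681	0.378257	-6.1178
AT1G01750	ADF11, actin depolymerizing factor 11	723.49	10.7564	-6.07171
AT3G21340	Leucine-rich repeat protein kinase family protein	83.7404	1.26439	-6.04941
AT2G30660	ATP-dependent caseinolytic (Clp) protease/crotonase	24.6728	0.377473	-6.0304
AT1G10385	Vps51/Vps67 (components of vesicular transport) protein	8.71123	0.133365	-6.02942
AT4G14780	Protein kinase superfamily protein	11.7601	0.181057	-6.02132
AT3G54870	ARK1, CAE1, MRH2	48.081	0.745398	-6.01131
AT3G47050	Glycosyl hydrolase family protein	10.9459	0.183671	-5.89713
AT2G38500	2-Oxoglutarate (2OG) and Fe(II)-dependent oxygenase	91.0314	1.52791	-5.89674
AT3G07900	O-fucosyltransferase family protein	32.1397	0.546227	-5.87871
AT5G15600	SP1L4, SPIRAL1-like4	148.905	2.58613	-5.84745
AT1G53680	ATGSTU28, GSTU28, glutathione S-transferase TAU 28	304.142	5.34615	-5.8301
AT5G42785	Unknown protein	80.0565	1.42305	-5.81396
AT2G20030	RING/U-box superfamily protein	8.41905	0.150287	-5.80787
AT2G03360	Glycosyltransferase family 61 protein	6.24031	0.112152	-5.79809
AT5G12050	Unknown protein	184.136	3.34175	-5.78402
AT4G22217	Arabidopsis defensin-like protein	349.124	6.59131	-5.72703
AT4G21200	ATGA2OX8, GA2OX8, gibberellin 2-oxidase 8	11.7754	0.22266	-5.72479
AT4G08450	Disease resistance protein (TIR-NBS-LRR class) family	7.34767	0.139961	-5.71419
AT1G18420	Aluminum activated malate transporter family protein	55.8597	1.08416	-5.68716
AT1G04280	P-loop containing nucleoside triphosphate hydrolases superfamily protein	192.645	3.74287	-5.68566
AT2G17590	Cysteine/Histidine-rich C1 domain family protein	4.31448	0.0844839	-5.67437
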