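gene	region	region_index	start	end	pattern	rpkm_rh	rpkm_nrh	log2fc
AT1G18460	promoter	0	2170	2154	AACGTGAACACCATGGA	142.28	60.44	-1.24
AT1G18470	promoter	0	831	815	AACGTGAAACACATGTT	104.71	48.45	-1.11
AT2G31350	promoter	0	1950	1966	ACTATGTGGATCACGTT	163.77	15.16	-3.43
AT2G33320	promoter	0	2495	2479	AACGTGAAAAACATAGA	9.96	3.39	-1.56
AT3G45530	promoter	0	344	328	AACGTGAAAACCAAAAA	3.22	0.09	-5.1
AT2G31350	intron	1	161	145	TACGTGATGATCATTTT	163.77	15.16	-3.43
AT3G19050	intron	19	25	41	TTCTTGTGCATCACGTA	0.47	4.6	3.29
AT4G03500	intron	1	856	840	TACGTGCTAAGCAAATT	16.3	2.45	-2.73
AT5G27680	intron	8	72	56	TACGTGCTATTCAAATT	0.18	2.15	3.59
AT1G18460	cds	0	1435	1451	AACATGTGTTTCACGTT	142.28	60.44	-1.24
AT1G18470	cds	0	466	482	TCCATGGTGTTCACGTT	104.71	48.45	-1.11
AT2G33320	cds	0	254	270	TCCGTGATGTTCACGTT	9.96	3.39	-1.56
AT3G19050	cds	0	2555	2571	ATTTTGAGCCGCACGAA	0.47	4.6	3.29
AT3G45530	cds	0	1442	1458	TCCATGGAAGTCACGAT	3.22	0.09	-5.1
AT4G03500	cds	0	1723	1739	TTTATGGCTGGCACGTA	16.3	2.45	-2.73
AT5G27680	cds	0	1241	1257	ATTTTGGTTCTCACGAT	0.18	2.15	3.59
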