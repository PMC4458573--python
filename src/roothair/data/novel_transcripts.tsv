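gene	locus	rpkm_rh	rpkm_nrh	log2fc	q_value
XLOC_000763	Chr1:5374818-5375862	23.2677	1.33563	-4.12273	0.00083917
XLOC_007957	Chr2:565024-566158	0	1.08437	inf	0.00083917
XLOC_013179	Chr3:872193-873509	0	2.1933	inf	0.00083917
XLOC_031350	Chrchloroplast:72259-88953	0.46923	5.2598	3.48665	0.00083917
XLOC_031361	Chrmitochondria:286411-363534	386.671	71.7074	-2.43091	0.00201438
XLOC_007668	Chr1:29208757-29210196	0	1.59459	inf	0.00346354
XLOC_007865	Chr1:17233557-17234225	0	0.583177	inf	0.00427705
XLOC_017836	Chr3:12558721-12560070	0	3.49622	inf	0.00427705
XLOC_008519	Chr2:4871295-4871915	0	1.02029	inf	0.0065152
XLOC_012898	Chr2:18797715-18799154	0	0.445751	inf	0.00997437
XLOC_026701	Chr5:20540459-20541185	1.4363	7.97303	2.47277	0.0321607
XLOC_005665	Chr1:12271087-12271679	13.8534	0.950421	-3.86553	0.033759
XLOC_007866	Chr1:17292409-17293002	48.231	16.1677	-1.57685	0.0422255
XLOC_026377	Chr5:17958314-17959838	5.63137	17.0462	1.59789	0.0482593
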