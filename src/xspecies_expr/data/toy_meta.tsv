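sample_id	species	tissue	replicate
arabiensis_MAG_1	arabiensis	MAG	1
arabiensis_MAG_2	arabiensis	MAG	2
arabiensis_MAG_3	arabiensis	MAG	3
arabiensis_TESTIS_1	arabiensis	TESTIS	1
arabiensis_TESTIS_2	arabiensis	TESTIS	2
arabiensis_TESTIS_3	arabiensis	TESTIS	3
coluzzii_MAG_1	coluzzii	MAG	1
coluzzii_MAG_2	coluzzii	MAG	2
coluzzii_MAG_3	coluzzii	MAG	3
coluzzii_TESTIS_1	coluzzii	TESTIS	1
coluzzii_TESTIS_2	coluzzii	TESTIS	2
coluzzii_TESTIS_3	coluzzii	TESTIS	3
gambiae_MAG_1	gambiae	MAG	1
gambiae_MAG_2	gambiae	MAG	2
gambiae_MAG_3	gambiae	MAG	3
gambiae_TESTIS_1	gambiae	TESTIS	1
gambiae_TESTIS_2	gambiae	TESTIS	2
gambiae_TESTIS_3	gambiae	TESTIS	3
merus_MAG_1	merus	MAG	1
merus_MAG_2	merus	MAG	2
merus_MAG_3	merus	MAG	3
merus_TESTIS_1	merus	TESTIS	1
merus_TESTIS_2	merus	TESTIS	2
merus_TESTIS_3	merus	TESTIS	3
quadriannulatus_MAG_1	quadriannulatus	MAG	1
quadriannulatus_MAG_2	quadriannulatus	MAG	2
quadriannulatus_MAG_3	quadriannulatus	MAG	3
quadriannulatus_TESTIS_1	quadriannulatus	TESTIS	1
quadriannulatus_TESTIS_2	quadriannulatus	TESTIS	2
quadriannulatus_TESTIS_3	quadriannulatus	TESTIS	3
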