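transcript_id	tissue_enriched_in	lineage_group	is_hvg	cluster
T00000			False	background
T00001			False	background
T00002			False	background
T00003			False	background
T00004		coluzzii+gambiae	False	lineage_coluzzii+gambiae
T00005	MAG		False	MAG_enriched
T00006			False	background
T00007		merus+quadriannulatus	False	lineage_merus+quadriannulatus
T00008			False	background
T00009			True	highly_variable
T00010			False	background
T00011			False	background
T00012			False	background
T00013			False	background
T00014			False	background
T00015			False	background
T00016			False	background
T00017	TESTIS		False	TESTIS_enriched
T00018		coluzzii+gambiae	False	lineage_coluzzii+gambiae
T00019			False	background
T00020	MAG		False	MAG_enriched
T00021			True	highly_variable
T00022			False	background
T00023		merus+quadriannulatus	False	lineage_merus+quadriannulatus
T00024		merus+quadriannulatus	False	lineage_merus+quadriannulatus
T00025	TESTIS		False	TESTIS_enriched
T00026			True	highly_variable
T00027	TESTIS		False	TESTIS_enriched
T00028			True	highly_variable
T00029		coluzzii+gambiae	False	lineage_coluzzii+gambiae
T00030			False	background
T00031		merus+quadriannulatus	False	lineage_merus+quadriannulatus
T00032			False	background
T00033			False	background
T00034			True	highly_variable
T00035			False	background
T00036			False	background
T00037		coluzzii+gambiae	False	lineage_coluzzii+gambiae
T00038		merus+quadriannulatus	False	lineage_merus+quadriannulatus
T00039	MAG		False	MAG_enriched
T00040		coluzzii+gambiae	False	lineage_coluzzii+gambiae
T00041			False	background
T00042			False	background
T00043			False	background
T00044			False	background
T00045	TESTIS		False	TESTIS_enriched
T00046	MAG		False	MAG_enriched
T00047	MAG		False	MAG_enriched
T00048			False	background
T00049	TESTIS		False	TESTIS_enriched
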