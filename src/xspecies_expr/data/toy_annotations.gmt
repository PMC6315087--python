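SYN:MAG_enriched	planted MAG_enriched group	T00005	T00020	T00039	T00046	T00047
SYN:TESTIS_enriched	planted TESTIS_enriched group	T00017	T00025	T00027	T00045	T00049
SYN:highly_variable	planted highly_variable group	T00009	T00021	T00026	T00028	T00034
SYN:lineage_coluzzii+gambiae	planted lineage_coluzzii+gambiae group	T00004	T00018	T00029	T00037	T00040
SYN:lineage_merus+quadriannulatus	planted lineage_merus+quadriannulatus group	T00007	T00023	T00024	T00031	T00038
SYN:oddset	synthetic null term (odd ids)	T00001	T00003	T00005	T00007	T00009	T00011	T00013	T00015	T00017	T00019	T00021	T00023	T00025	T00027	T00029	T00031	T00033	T00035	T00037	T00039	T00041	T00043	T00045	T00047	T00049
SYN:firsthalf	synthetic null term (first half)	T00000	T00001	T00002	T00003	T00004	T00005	T00006	T00007	T00008	T00009	T00010	T00011	T00012	T00013	T00014	T00015	T00016	T00017	T00018	T00019	T00020	T00021	T00022	T00023	T00024
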