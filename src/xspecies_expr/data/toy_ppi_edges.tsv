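T00000	T00002
T00000	T00008
T00000	T00009
T00000	T00011
T00000	T00014
T00000	T00015
T00000	T00030
T00000	T00035
T00000	T00043
T00000	T00044
T00001	T00006
T00001	T00009
T00001	T00010
T00001	T00011
T00001	T00013
T00001	T00016
T00001	T00019
T00001	T00030
T00001	T00032
T00001	T00033
T00001	T00035
T00001	T00036
T00001	T00041
T00001	T00043
T00001	T00044
T00002	T00006
T00002	T00011
T00002	T00015
T00002	T00016
T00002	T00022
T00002	T00030
T00002	T00036
T00002	T00039
T00002	T00043
T00002	T00045
T00002	T00047
T00002	T00048
T00003	T00006
T00003	T00010
T00003	T00012
T00003	T00013
T00003	T00015
T00003	T00019
T00003	T00022
T00003	T00032
T00003	T00033
T00003	T00035
T00003	T00036
T00003	T00041
T00003	T00044
T00003	T00045
T00004	T00020
T00004	T00029
T00004	T00037
T00004	T00039
T00005	T00020
T00005	T00023
T00005	T00039
T00006	T00010
T00006	T00012
T00006	T00013
T00006	T00015
T00006	T00019
T00006	T00032
T00006	T00033
T00006	T00042
T00006	T00044
T00006	T00048
T00007	T00023
T00007	T00031
T00008	T00013
T00008	T00014
T00008	T00019
T00008	T00032
T00008	T00035
T00008	T00038
T00008	T00041
T00008	T00042
T00009	T00021
T00009	T00026
T00009	T00028
T00009	T00040
T00009	T00047
T00010	T00014
T00010	T00015
T00010	T00016
T00010	T00030
T00010	T00043
T00010	T00044
T00010	T00048
T00011	T00015
T00011	T00016
T00011	T00019
T00011	T00022
T00011	T00026
T00011	T00032
T00012	T00013
T00012	T00029
T00012	T00036
T00012	T00042
T00012	T00043
T00012	T00048
T00012	T00049
T00013	T00014
T00013	T00015
T00013	T00016
T00013	T00019
T00013	T00026
T00013	T00030
T00013	T00032
T00013	T00035
T00013	T00036
T00013	T00042
T00013	T00048
T00014	T00019
T00014	T00024
T00014	T00032
T00014	T00034
T00014	T00035
T00014	T00036
T00014	T00041
T00014	T00043
T00014	T00048
T00015	T00016
T00015	T00018
T00015	T00028
T00015	T00032
T00015	T00041
T00015	T00043
T00015	T00048
T00016	T00019
T00016	T00022
T00016	T00041
T00016	T00048
T00017	T00027
T00017	T00045
T00017	T00046
T00017	T00049
T00018	T00029
T00018	T00040
T00019	T00022
T00019	T00027
T00019	T00030
T00019	T00036
T00019	T00041
T00019	T00043
T00019	T00044
T00020	T00039
T00020	T00047
T00021	T00026
T00021	T00041
T00022	T00030
T00022	T00032
T00022	T00033
T00022	T00036
T00022	T00037
T00022	T00041
T00022	T00042
T00022	T00048
T00023	T00032
T00023	T00038
T00023	T00040
T00023	T00043
T00024	T00026
T00024	T00030
T00024	T00038
T00025	T00027
T00025	T00030
T00026	T00034
T00027	T00035
T00027	T00045
T00029	T00037
T00029	T00040
T00030	T00033
T00030	T00036
T00030	T00043
T00031	T00038
T00032	T00033
T00032	T00041
T00032	T00042
T00032	T00043
T00032	T00044
T00033	T00036
T00033	T00041
T00035	T00043
T00035	T00049
T00036	T00037
T00036	T00041
T00036	T00043
T00036	T00046
T00036	T00048
T00037	T00040
T00037	T00046
T00039	T00047
T00041	T00042
T00041	T00043
T00041	T00047
T00042	T00044
T00043	T00048
T00045	T00048
T00046	T00047
T00046	T00049
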