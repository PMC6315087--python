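transcript_id	omega
T00000	0.20932275974887518
T00001	0.14725892414504299
T00002	0.11929626817679939
T00003	0.067945516985372115
T00004	0
T00005	0
T00006	0.075468726715426745
T00007	0.060947878665943082
T00008	0.089464104319318782
T00009	0.3963466558665299
T00010	0.053387104496521662
T00011	0.4981550916886287
T00012	0.43606001922769927
T00013	1.2208197862479979
T00014	0.20111503617559456
T00015	0.20737581720700857
T00016	0.053073771210625557
T00017	0
T00018	0
T00019	0.095004543353060938
T00020	0
T00021	0.13033345769213095
T00022	0.17403202546430235
T00023	0.66195045204660952
T00024	0
T00025	0
T00026	0.05011043421802272
T00027	0
T00028	0.20475076670698672
T00029	0.2191225132297856
T00030	0.080287529884171316
T00031	0.28939502990724997
T00032	0.23502119439131425
T00033	0.21618673795100565
T00034	0.90650221733705361
T00035	0.068479352130178306
T00036	0
T00037	0.36476109265450707
T00038	0.52580859594388851
T00039	0.10683006307306583
T00040	0.29086530504900587
T00041	0
T00042	0.15562375940624823
T00043	0
T00044	0.031550307221986769
T00045	0
T00046	0
T00047	0.044207559061938823
T00048	0.18559258017532121
T00049	0.3843278968799102
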