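sample_id	factor
arabiensis_MAG_1	0.67384444653803388
arabiensis_MAG_2	1.6461801966295775
arabiensis_MAG_3	0.84463564991907647
arabiensis_TESTIS_1	1.6283878537834979
arabiensis_TESTIS_2	0.69901687822601255
arabiensis_TESTIS_3	1.1788018452159257
coluzzii_MAG_1	1.8066799726348315
coluzzii_MAG_2	0.71488744381940261
coluzzii_MAG_3	1.3066322750057981
coluzzii_TESTIS_1	1.9651306607857604
coluzzii_TESTIS_2	0.61608297542129187
coluzzii_TESTIS_3	0.56518872138841714
gambiae_MAG_1	1.2731393927868646
gambiae_MAG_2	0.8007766963026326
gambiae_MAG_3	0.55190388826563397
gambiae_TESTIS_1	0.96634566000758526
gambiae_TESTIS_2	1.4216253961863385
gambiae_TESTIS_3	0.74238774521135642
merus_MAG_1	0.79558818418546784
merus_MAG_2	1.6148484766405535
merus_MAG_3	1.0282163260390498
merus_TESTIS_1	1.6082190646807522
merus_TESTIS_2	0.92837461774606123
merus_TESTIS_3	1.8737783720941077
quadriannulatus_MAG_1	1.2325013095052961
quadriannulatus_MAG_2	0.58714866016243683
quadriannulatus_MAG_3	1.7054896224206226
quadriannulatus_TESTIS_1	0.98522857842299227
quadriannulatus_TESTIS_2	0.60847839170303342
quadriannulatus_TESTIS_3	0.61787215675467766
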