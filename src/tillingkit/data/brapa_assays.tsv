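# Raw columns of eight TILLING assays in the B. rapa R-o-18 EMS population.
# Six amplicons screened on the 0.3% EMS population, two on the 0.4% population.
# All derived quantities (densities, loads, expected yields) are recomputed by
# tillingkit.screen_stats; only raw observations are stored here.  Note the
# published density for BraA.RPL.c at 0.4% was misprinted as "1/358"; the raw
# columns below give 1001*2304/40 = 57,658 bp, i.e. 1/58.
gene	ems_pct	length_bp	gc_pct	mutations	screened	population
BraA.RPL.a	0.3	1007	47	21	768	6912
BraA.RPL.b	0.3	1072	45	149	4608	6912
BraA.RPL.c	0.3	1001	47	132	4608	6912
BraA.IND.a	0.3	1004	41	35	3072	6912
BraA.MET1.a	0.3	1104	48	94	3072	6912
BraA.MET2.b	0.3	1007	47	89	3072	6912
BraA.RPL.b	0.4	1072	45	57	2304	2304
BraA.RPL.c	0.4	1001	47	40	2304	2304
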