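# Observed mutation-class counts and heterozygous:homozygous ratios per assay
# in the B. rapa EMS population (confirmed mutations after sequencing).
gene	ems_pct	silent	missense	nonsense	het_hom_ratio
BraA.RPL.a	0.3	8	12	1	9.5
BraA.RPL.b	0.3	30	46	0	8.5
BraA.RPL.c	0.3	27	71	0	7.2
BraA.IND.a	0.3	10	22	1	15.5
BraA.MET1.a	0.3	11	4	2	16.0
BraA.MET2.b	0.3	4	12	1	16.0
BraA.RPL.b	0.4	2	15	2	5.3
BraA.RPL.c	0.4	13	12	0	5.3
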