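phage	clade	host	genome_bp	gc_pct	orfs	accession
P-SCSP1a	MPP-C	Prochlorococcus MED4	37777	38.7	36	OM416763
P-SCSP1b	MPP-C	Prochlorococcus MED4	37821	38.8	40	OM416764
P-SCSP1c	MPP-C	Prochlorococcus MED4	37789	38.8	36	OM416765
P-SCSP1d	MPP-C	Prochlorococcus MED4	37752	38.8	36	OM416766
P-SCSP1f	MPP-C	Prochlorococcus MED4	37858	38.7	39	OM416767
P-SCSP1g	MPP-C	Prochlorococcus MED4	37811	38.7	40	OM416768
P-SCSP1h	MPP-C	Prochlorococcus MED4	37844	38.7	40	OM416769
P-SCSP1i	MPP-C	Prochlorococcus MED4	37812	38.7	40	OM416770
P-SCSP1k	MPP-C	Prochlorococcus MED4	37771	38.7	37	OM416771
P-SCSP1l	MPP-C	Prochlorococcus MED4	37821	38.7	40	OM416772
P-SCSP1m	MPP-C	Prochlorococcus MED4	37812	38.7	40	OM416773
P-SCSP1n	MPP-C	Prochlorococcus MED4	37812	38.7	40	OM416774
P-SCSP1o	MPP-C	Prochlorococcus MED4	37752	38.8	36	OM416775
P-SCSP1p	MPP-C	Prochlorococcus MED4	37844	38.7	39	OM416776
P-SCSP1q	MPP-C	Prochlorococcus MED4	37754	38.7	40	OM416777
P-SCSP1s	MPP-C	Prochlorococcus MED4	37849	38.7	39	OM416778
P-SCSP1u	MPP-C	Prochlorococcus MED4	37861	38.7	38	OM416779
P-SCSP2	MPP-C	Prochlorococcus MED4	37264	34.2	44	OM416780
P-RSP2	P-RSP2	Prochlorococcus MIT9302	42257	34.0	48	HQ332139
P60	MPP-A	Synechococcus WH7805	46675	53.3	55	AF338467
Syn5	MPP-A	Synechococcus WH8019	46214	55.0	61	EF372997
S-CBP2	MPP-A	Synechococcus CB0208	46237	55.0	53	KC310806
S-CBP42	MPP-A	Synechococcus WH7803	45218	54.6	57	KC310805
P-SSP9	MPP-A	Prochlorococcus SS120	46997	40.5	54	HQ316584
P-SSP7	MPP-B	Prochlorococcus MED4	44970	38.8	54	AY939843
P-SSP5	MPP-B	Prochlorococcus MIT9515	47055	39.2	55	GU071100
P-RSP5	MPP-B	Prochlorococcus NATL1A	47741	38.7	68	GU071102
P-HP1	MPP-B	Prochlorococcus NATL2A	47536	39.9	66	GU071104
P-SSP2	MPP-B	Prochlorococcus MIT9312	45890	37.9	59	GU071107
P-GSP1	MPP-B	Prochlorococcus MED4	44945	39.6	53	HQ332140
P-SSP3	MPP-B	Prochlorococcus MIT9312	46198	37.9	56	HQ332137
P-SSP10	MPP-B	Prochlorococcus NATL2A	47325	39.2	52	HQ337022
P-SSP6	MPP-B	Prochlorococcus MIT9515	47039	39.2	54	HQ634152
S-CBP1	MPP-B	Synechococcus CB0101	46547	47.6	51	KC310802
S-CBP3	MPP-B	Synechococcus CB0101	45871	47.0	55	KC310803
S-CBP4	MPP-B	Synechococcus CB0101	44147	44.4	49	KC310804
S-RIP1	MPP-B	Synechococcus WH8101	44892	42.9	54	HQ317388
S-RIP2	MPP-B	Synechococcus WH7803	45728	47.3	56	HQ317389
S-SBP1	MPP-B	Synechococcus WH7803	45519	46.8	55	MT424636
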