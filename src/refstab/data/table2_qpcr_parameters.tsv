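gene	product_length_bp	efficiency	mean_cq	sd_cq	cv_pct	rank_by_cv
UBQ1	126	2.07	22.48	0.52	2.31	4
COG	104	1.99	23.12	0.47	2.03	1
TMN	124	2.06	20.78	0.45	2.16	2
CDC42	104	1.98	21.69	0.70	3.23	12
ARL	111	2.01	21.92	0.59	2.69	8
TMED	128	1.97	21.77	0.57	2.62	7
RhoA	102	1.99	19.91	0.54	2.71	9
MOB	132	1.94	21.85	0.49	2.24	3
RPS15	110	1.82	16.46	0.48	2.92	10
RPL17	123	1.83	16.49	0.39	2.36	5
UBQ2	125	2.23	21.03	0.53	2.52	6
TubA	129	2.11	19.37	0.62	3.20	11
TubB	125	1.98	16.74	0.83	4.96	14
GAPDH	123	2.00	19.28	0.84	4.36	13
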