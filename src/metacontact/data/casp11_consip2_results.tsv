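domain	length	precision	neff
T0761-D1	88	5.6	1
T0761-D2	136	8.7	1
T0763-D1	130	46.2	2
T0767-D2	180	58.3	43
T0771-D1	151	10.0	8
T0775-D2	66	46.2	19
T0775-D4	61	25.0	20
T0775-D5	145	0.0	14
T0777-D1	345	23.2	39
T0781-D1	200	5.0	2
T0785-D1	112	18.2	1
T0789-D1	146	51.7	253
T0789-D2	126	28.0	304
T0790-D1	135	44.4	276
T0790-D2	130	26.9	300
T0791-D1	156	53.3	223
T0791-D2	139	42.9	271
T0793-D1	109	15.0	302
T0793-D2	45	11.1	402
T0793-D5	118	38.1	357
T0794-D2	172	26.5	133
T0799-D1	141	7.1	2
T0802-D1	116	13.0	4
T0804-D2	152	16.7	1
T0806-D1	256	84.3	561
T0808-D2	269	35.2	46
T0810-D1	113	17.4	83
T0814-D1	137	37.0	115
T0814-D2	116	82.6	131
T0820-D1	90	5.6	1
T0824-D1	108	45.5	155
T0826-D1	201	7.5	422
T0827-D2	158	10.0	257
T0831-D2	244	7.7	71
T0832-D1	209	2.4	10
T0834-D1	99	5.0	34
T0834-D2	92	17.7	28
T0836-D1	204	43.9	50
T0837-D1	121	29.2	9
T0855-D1	115	17.4	19
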