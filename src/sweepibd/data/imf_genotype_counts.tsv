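population	n	imf_mean	imf_sd	n_CC	n_CA	n_AA
Min	19	5.25	0.12	11	7	1
Zaozhuang_heigai	30	4.48		18	11	1
Shaziling	20	3.27	1.07	19	1	0
Daweizi	5	5.57	0.15	2	3	0
Ningxiang	7	4.04	0.42	6	1	0
Jinhua	26	3.7	0.43	23	3	0
Xiaomeishang	21	4.87		21	0	0
Lantang	30	5.21	0.33	29	1	0
Putian	27	4.43	0.09	22	5	0
Enshi	26	4.32	0.68	25	1	0
Neijiang	7	5.42		7	0	0
Tibet	20	4.71	0.59	13	7	0
Yorkshire	38	3.20	0.13	15	17	6
Berkshire	10	3.68	0.99	3	4	3
Landrace	10	1.84	0.09	1	3	6
Jiangquhai	4	6.18	1.40	4	0	0
Leping	2	2.17	0.46	2	0	0
Chuanxiang	2	4.17	0.45	2	0	0
Rongchang	5	3.67	2.02	5	0	0
Wannan	2	3.37	0.13	2	0	0
Duroc	41	2.71	0.08	0	11	30
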