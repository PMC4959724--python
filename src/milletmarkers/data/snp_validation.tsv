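locus	maf	gene_diversity	heterozygosity	pic_all	pic_wild	pic_cultivated
ICECSNT2	0.70	0.42	0.057	0.33	0.18	NA
ICECSNT3	0.98	0.03	0.034	0.03	0.09	NA
ICECSNT4	0.76	0.37	0.077	0.30	0.23	0.02
ICECSNT5	0.54	0.50	0.857	0.37	0.37	0.37
ICECSNT6	0.52	0.50	0.966	0.37	0.37	NA
ICECSNT8	0.51	0.50	0.955	0.37	0.37	0.37
ICECSNT9	0.52	0.50	0.966	0.37	0.37	NA
ICECSNT11	0.52	0.50	0.966	0.37	0.37	NA
ICECSNT12	0.85	0.25	0.092	0.22	0.37	0.03
ICECSNT13	0.92	0.15	0.045	0.14	0.27	NA
ICECSNT14	0.52	0.50	0.966	0.37	0.37	0.03
ICECSNT15	0.97	0.07	0.000	0.06	0.16	NA
ICECSNT16	0.52	0.50	0.966	0.37	0.37	NA
ICECSNT17	0.51	0.50	0.977	0.37	0.37	NA
ICECSNT18	0.70	0.42	0.081	0.33	0.22	NA
ICECSNT20	0.51	0.50	0.943	0.37	0.37	NA
ICECSNT22	0.75	0.38	0.082	0.31	0.29	NA
ICECSNT23	0.51	0.50	0.977	0.37	0.37	NA
ICECSNT24	0.74	0.38	0.060	0.31	0.21	NA
ICECSNT26	0.50	0.50	0.977	0.38	0.38	NA
ICECSNT27	0.52	0.50	0.954	0.37	0.37	0.37
ICECSNT28	0.51	0.50	0.966	0.37	0.37	NA
ICECSNT31	0.52	0.50	0.966	0.37	0.37	NA
ICECSNT32	0.67	0.44	0.038	0.34	0.19	0.16
ICECSNT33	0.99	0.01	0.011	0.01	NA	0.02
ICECSNT34	0.51	0.50	0.989	0.37	0.37	NA
ICECSNT35	0.58	0.49	0.000	0.37	0.18	0.27
ICECSNT36	0.69	0.43	0.047	0.34	0.22	0.12
ICECSNT38	0.96	0.08	0.011	0.07	0.17	0.02
ICECSNT39	0.70	0.42	0.045	0.33	0.20	NA
ICECSNT40	0.99	0.02	0.000	0.02	0.06	NA
ICECSNT41	0.52	0.50	0.966	0.37	0.37	NA
ICECSNT42	0.62	0.47	0.713	0.36	0.17	NA
ICECSNT43	0.52	0.50	0.964	0.37	0.37	NA
ICECSNT44	0.52	0.50	0.966	0.37	0.37	NA
ICECSNT45	0.61	0.48	0.778	0.36	0.19	NA
ICECSNT46	0.99	0.01	0.012	0.01	0.03	NA
ICECSNT47	0.52	0.50	0.966	0.37	0.37	NA
ICECSNT48	0.52	0.50	0.913	0.37	0.37	0.37
ICECSNT49	0.88	0.21	0.171	0.19	0.36	0.02
ICECSNT51	0.61	0.47	0.722	0.36	0.19	NA
ICECSNT52	0.89	0.20	0.150	0.18	0.37	NA
ICECSNT53	0.51	0.50	0.977	0.37	0.37	NA
ICECSNT54	0.97	0.07	0.000	0.06	0.16	NA
ICECSNT55	0.74	0.39	0.482	0.31	0.38	0.21
ICECSNT56	0.54	0.50	0.871	0.37	0.36	NA
ICECSNT57	0.51	0.50	0.966	0.37	0.37	NA
ICECSNT58	0.51	0.50	0.951	0.37	0.38	0.37
ICECSNT59	0.96	0.07	0.000	0.07	0.17	NA
ICECSNT61	0.63	0.47	0.744	0.36	0.08	NA
ICECSNT62	0.70	0.42	0.000	0.33	0.12	NA
ICECSNT66	0.82	0.29	0.000	0.25	0.33	NA
ICECSNT67	0.97	0.07	0.000	0.06	0.17	NA
ICECSNT68	0.52	0.50	0.965	0.37	0.37	NA
ICECSNT69	0.98	0.05	0.000	0.04	0.12	NA
ICECSNT72	0.97	0.07	0.023	0.06	NA	0.09
ICECSNT73	0.52	0.50	0.966	0.37	0.37	NA
ICECSNT76	0.52	0.50	0.966	0.37	0.37	NA
ICECSNT77	0.72	0.40	0.069	0.32	0.24	NA
ICECSNT78	0.99	0.01	0.011	0.01	NA	0.02
ICECSNT79	0.94	0.11	0.000	0.11	0.26	NA
ICECSNT80	0.51	0.50	0.989	0.37	0.37	NA
ICECSNT81	0.52	0.50	0.966	0.37	0.37	NA
ICECSNT82	0.52	0.50	0.965	0.37	0.37	NA
ICECSNT83	0.69	0.43	0.198	0.34	0.30	0.16
ICECSNT84	0.52	0.50	0.966	0.37	0.37	NA
ICECSNT85	0.67	0.44	0.074	0.35	0.20	0.11
ICECSNT86	0.85	0.25	0.115	0.22	0.37	NA
ICECSNT88	0.55	0.49	0.894	0.37	0.34	NA
ICECSNT89	0.51	0.50	0.977	0.37	0.37	NA
ICECSNT90	0.75	0.38	0.061	0.30	0.22	NA
ICECSNT91	0.52	0.50	0.966	0.37	0.37	NA
ICECSNT93	0.72	0.40	0.000	0.32	0.29	0.15
ICECSNT94	0.50	0.50	0.977	0.38	0.38	NA
ICECSNT95	0.80	0.32	0.267	0.27	0.37	0.03
ICECSNT96	0.80	0.32	0.179	0.27	0.35	NA
ICECSNT99	0.52	0.50	0.966	0.37	0.37	NA
ICECSN99	0.99	0.01	0.011	0.01	NA	0.02
ICECSN100	0.52	0.50	0.966	0.37	0.37	NA
ICECSNT100	0.52	0.50	0.966	0.37	0.37	NA
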