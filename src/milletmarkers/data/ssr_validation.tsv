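marker	maf	allele_number	gene_diversity	pic
ICECP54	0.30	6	0.80	0.77
ICECP47	0.29	5	0.78	0.74
ICECP89	0.35	5	0.72	0.67
ICECP50	0.45	4	0.68	0.62
ICECP58	0.50	4	0.66	0.61
ICECP84	0.45	4	0.67	0.60
ICECP5	0.50	4	0.64	0.57
ICECP96	0.44	3	0.64	0.57
ICECP3	0.50	3	0.61	0.54
ICECP95	0.60	4	0.58	0.54
ICECP4	0.55	3	0.60	0.53
ICECP68	0.60	3	0.56	0.50
ICECP73	0.50	3	0.58	0.49
ICECP53	0.60	3	0.54	0.47
ICECP63	0.60	3	0.54	0.47
ICECP64	0.60	3	0.54	0.47
ICECP90	0.60	3	0.54	0.47
ICECP61	0.70	4	0.48	0.45
ICECP62	0.70	4	0.48	0.45
ICECP37	0.70	3	0.46	0.41
ICECP69	0.70	3	0.46	0.41
ICECP66	0.75	4	0.42	0.39
ICECP11	0.50	2	0.50	0.38
ICECP67	0.50	2	0.50	0.38
ICECP70	0.50	2	0.50	0.38
ICECP71	0.50	2	0.50	0.38
ICECP97	0.50	2	0.50	0.38
ICECP46	0.57	2	0.49	0.37
ICECP40	0.60	2	0.48	0.36
ICECP85	0.60	2	0.48	0.36
ICECP98	0.60	2	0.48	0.36
ICECP99	0.60	2	0.48	0.36
ICECP42	0.63	2	0.47	0.36
ICECP44	0.67	2	0.44	0.35
ICECP59	0.67	2	0.44	0.35
ICECP82	0.67	2	0.44	0.35
ICECP92	0.67	2	0.44	0.35
ICECP93	0.78	3	0.37	0.34
ICECP56	0.70	2	0.42	0.33
ICECP52	0.71	2	0.41	0.32
ICECP72	0.80	3	0.34	0.31
ICECP80	0.80	3	0.34	0.31
ICECP101	0.80	3	0.34	0.31
ICECP1	0.75	2	0.38	0.30
ICECP43	0.80	2	0.32	0.27
ICECP48	0.89	2	0.20	0.18
ICECP57	0.90	2	0.18	0.16
ICECP81	0.90	2	0.18	0.16
ICECP91	0.90	2	0.18	0.16
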