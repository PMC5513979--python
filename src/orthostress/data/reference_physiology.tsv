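species	treatment	variable	mean	cv
A_monilatum	replete	growth_rate	0.26	0.10
A_monilatum	lowN	growth_rate	0.20	0.17
A_monilatum	lowP	growth_rate	0.22	0.26
A_monilatum	replete	POC	781.7	0.08
A_monilatum	lowN	POC	1328	0.05
A_monilatum	lowP	POC	1186	0.06
A_monilatum	replete	PON	175.3	0.04
A_monilatum	lowN	PON	187.3	0.03
A_monilatum	lowP	PON	222.1	0.10
A_monilatum	replete	CN	4.5	0.05
A_monilatum	lowN	CN	7.1	0.07
A_monilatum	lowP	CN	5.4	0.04
A_monilatum	replete	pCHO	402	0.31
A_monilatum	lowN	pCHO	213	0.20
A_monilatum	lowP	pCHO	856	0.39
A_monilatum	replete	chl_a	4.9e-05	0.67
A_monilatum	lowN	chl_a	8.5e-05	0.11
A_monilatum	lowP	chl_a	5.9e-05	0.74
P_minimum	replete	growth_rate	0.48	0.05
P_minimum	lowN	growth_rate	0.33	0.04
P_minimum	lowP	growth_rate	0.34	0.01
P_minimum	replete	POC	34.2	0.17
P_minimum	lowN	POC	59.7	0.14
P_minimum	lowP	POC	73.4	0.04
P_minimum	replete	PON	3.3	0.21
P_minimum	lowN	PON	2.5	0.08
P_minimum	lowP	PON	4.1	0.06
P_minimum	replete	CN	11.9	0.04
P_minimum	lowN	CN	23.9	0.18
P_minimum	lowP	CN	18.0	0.02
P_minimum	replete	pCHO	28.4	0.55
P_minimum	lowN	pCHO	43.7	0.30
P_minimum	lowP	pCHO	53.9	0.01
P_minimum	replete	chl_a	1.3e-06	0.31
P_minimum	lowN	chl_a	1.3e-06	0.28
P_minimum	lowP	chl_a	2.4e-06	0.22
P_minimum	replete	FvFm	0.59	0.05
P_minimum	lowN	FvFm	0.58	0.02
P_minimum	lowP	FvFm	0.55	0.02
C_affinis	replete	growth_rate	0.80	0.06
C_affinis	lowN	growth_rate	0.57	0.02
C_affinis	lowP	growth_rate	0.62	0.01
C_affinis	replete	POC	14.1	0.05
C_affinis	lowN	POC	13.2	0.12
C_affinis	lowP	POC	10.0	0.64
C_affinis	replete	PON	2.1	0.06
C_affinis	lowN	PON	0.96	0.17
C_affinis	lowP	PON	0.97	0.61
C_affinis	replete	CN	6.8	0.05
C_affinis	lowN	CN	12.0	0.26
C_affinis	lowP	CN	9.9	0.12
C_affinis	replete	pCHO	5.6	0.50
C_affinis	lowN	pCHO	10.7	0.06
C_affinis	lowP	pCHO	7.1	0.02
C_affinis	replete	chl_a	3.1e-06	0.11
C_affinis	lowN	chl_a	5.3e-07	0.08
C_affinis	lowP	chl_a	1.9e-06	0.06
C_affinis	replete	FvFm	0.66	0.04
C_affinis	lowN	FvFm	0.36	0.05
C_affinis	lowP	FvFm	0.66	0.01
C_polylepis	replete	growth_rate	0.33	0.05
C_polylepis	lowN	growth_rate	0.21	0.03
C_polylepis	lowP	growth_rate	0.23	0.07
C_polylepis	replete	POC	45.1	0.64
C_polylepis	lowN	POC	52.5	0.28
C_polylepis	lowP	POC	56.9	0.49
C_polylepis	replete	PON	5.5	0.55
C_polylepis	lowN	PON	5.1	0.26
C_polylepis	lowP	PON	6.3	0.46
C_polylepis	replete	CN	7.6	0.21
C_polylepis	lowN	CN	10.2	0.03
C_polylepis	lowP	CN	8.9	0.05
C_polylepis	replete	pCHO	24.3	0.21
C_polylepis	lowN	pCHO	28.1	0.33
C_polylepis	lowP	pCHO	34.0	0.65
C_polylepis	replete	chl_a	6.5e-06	0.78
C_polylepis	lowN	chl_a	6.8e-06	0.23
C_polylepis	lowP	chl_a	9.0e-06	0.48
C_polylepis	replete	FvFm	0.46	0.27
C_polylepis	lowN	FvFm	0.42	0.14
C_polylepis	lowP	FvFm	0.44	0.02
G_oceanica	replete	growth_rate	0.83	0.14
G_oceanica	lowN	growth_rate	0.55	0.02
G_oceanica	lowP	growth_rate	0.45	0.06
G_oceanica	replete	POC	0.64	0.61
G_oceanica	lowN	POC	0.85	0.01
G_oceanica	lowP	POC	1.01	0.02
G_oceanica	replete	PON	0.067	0.61
G_oceanica	lowN	PON	0.069	0.03
G_oceanica	lowP	PON	0.044	0.04
G_oceanica	replete	CN	9.6	0.03
G_oceanica	lowN	CN	19.4	0.04
G_oceanica	lowP	CN	14.6	0.04
G_oceanica	replete	pCHO	0.17	0.80
G_oceanica	lowN	pCHO	0.24	0.04
G_oceanica	lowP	pCHO	0.37	0.11
G_oceanica	replete	chl_a	1.02e-07	0.71
G_oceanica	lowN	chl_a	5.95e-08	0.10
G_oceanica	lowP	chl_a	8.07e-08	0.13
G_oceanica	replete	FvFm	0.67	0.02
G_oceanica	lowN	FvFm	0.62	0.03
G_oceanica	lowP	FvFm	0.64	0.02
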