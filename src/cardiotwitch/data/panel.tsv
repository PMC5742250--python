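drug	clinical_tdp	n_cells	n_hearts	fetpc_um	conc1_um	conc2_um	conc3_um	conc4_um	fold1	fold2	fold3	fold4	cipa
Ajmaline	positive	5	1	0.065	0.065	0.195	0.65	1.95	1	3	10	30	0
Astemizole	positive	4	1	0.0003	0.0003	0.0009	0.003	0.009	1	3	10	30	1
Azimilide	positive	6	1	0.07	0.07	0.21	0.7	2.1	1	3	10	30	1
Bepridil	positive	7	1	0.032	0.032	0.096	0.32	0.96	1	3	10	30	1
Chlorpromazine	positive	8	2	0.0345	0.0345	0.1035	0.345	1.035	1	3	10	30	1
Cisapride	positive	7	2	0.00258	0.00258	0.0258	0.0774	0.258	1	10	30	100	1
Clarithromycin	positive	8	2	1.2	1.2	12	36	120	1	10	30	100	1
Clozapine	positive	4	1	0.071	0.071	0.213	0.71	2.13	1	3	10	30	1
D,L-Sotalol	positive	8	2	14.7	1.5	15	150	450	0.1	1	10	30	1
Disopyramide	positive	7	2	0.7	0.7	2.1	7	21	1	3	10	30	1
Dofetilide	positive	6	1	0.002	0.002	0.02	0.06	0.22	1	10	30	100	1
Domperidone	positive	8	1	0.02	0.02	0.2	0.6	2	1	10	30	100	1
Droperidol	positive	4	1	0.016	0.016	0.048	0.16	0.48	1	3	10	30	1
Erythromycin	positive	7	1	0.17	0.17	0.51	1.7	5.1	1	3	10	30	0
Flecainide	positive	3	1	0.753	0.753	2.259	7.53	22.59	1	3	10	30	0
Ibutilide	positive	4	1	0.1	0.1	0.3	1	3	1	3	10	30	1
Moxifloxacin	positive	5	1	10.96	10.96	32.88	109.6	328.8	1	3	10	30	0
Ondansetron	positive	4	1	0.372	0.372	1.116	3.72	11.16	1	3	10	30	1
Procainamide	positive	4	1	54.186	54.186	162.558	541.86	1625.58	1	3	10	30	0
Quinidine	positive	4	1	3	0.3	3	30	100	0.1	1	10	30	1
Sematilide	positive	6	1	4.449	4.449	13.347	44.49	133.47	1	3	10	30	0
Terodiline	positive	4	1	0.145	0.145	0.435	1.45	4.35	1	3	10	30	0
Vandetanib	positive	4	1	0.3	0.3	0.9	3	9	1	3	10	30	1
Diltiazem	negative	4	1	0.128	0.128	0.384	1.28	3.84	1	3	10	30	1
Diphenhydramine	negative	5	1	0.034	0.034	0.102	0.34	1.02	1	3	10	30	0
Loratadine	negative	4	1	0.00045	0.00045	0.00135	0.0045	0.0135	1	3	10	30	1
Mexiletine	negative	7	1	2.5	0.25	2.5	25	75	0.1	1	10	30	1
Mibefradil	negative	6	1	0.012	0.012	0.036	0.12	0.36	1	3	10	30	0
Nifedipine	negative	4	1	0.0077	0.0077	0.0231	0.077	0.231	1	3	10	30	1
Nitrendipine	negative	4	1	0.00302	0.00302	0.00906	0.0302	0.0906	1	3	10	30	1
Ranolazine	negative	3	1	2	2	20	60	200	1	10	30	100	1
Tamoxifen	negative	6	1	0.0221	0.0221	0.0663	0.221	0.663	1	3	10	30	1
Verapamil	negative	4	1	0.045	0.01	0.1	1	10	0.2	2	22	222	1
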