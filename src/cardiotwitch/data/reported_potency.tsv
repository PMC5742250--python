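drug	top_conc_um	effect	ic50_um	ic50_censored	printed_ratio	ratio_censored
Ajmaline	1.95	-ve inotrope	2	0	31	0
Astemizole	0.009	No effect		1	30	0
Azimilide	2.1	-ve inotrope	1.07	0	15	0
Bepridil	0.96	-ve inotrope	0.7	0	22	0
Chlorpromazine	1.04	-ve inotrope	1.02	0	28	0
Cisapride	0.26	-ve inotrope	0.02	0	8	0
Clarithromycin	120	-ve inotrope	16	0	13	0
Clozapine	2.13	-ve inotrope	1.5	0	21	0
D,L-Sotalol	450	No effect		1	30	1
Disopyramide	21	-ve inotrope	9.3	0	13	0
Dofetilide	0.2	No effect		1	100	1
Domperidone	2	-ve inotrope	0.2	0	10	0
Droperidol	0.48	-ve inotrope	0.18	0	11	0
Erythromycin	5.1	No effect		1	30	1
Flecainide	22.6	-ve inotrope	1.1	0	2	0
Ibutilide	3	-ve inotrope	2	0	20	0
Moxifloxacin	329	No effect		1	30	1
Ondansetron	11.2	-ve inotrope	14	0	34	0
Procainamide	1625	-ve inotrope	2215	0	38	0
Quinidine	100	-ve inotrope	3.6	0	1	0
Sematilide	133	No effect		1	30	1
Terodiline	4.35	-ve inotrope	0.7	0	5	0
Vandetanib	9	-ve inotrope	2.7	0	9	0
Diltiazem	3.84	-ve inotrope	1	0	8	0
Diphenhydramine	1.02	-ve inotrope	0.6	0	17	0
Loratadine	0.0135	-ve inotrope	0.0175	0	35	0
Mexiletine	75	-ve inotrope	0.9	0	0.4	0
Mibefradil	0.36	-ve inotrope	0.18	0	13	0
Nifedipine	0.23	-ve inotrope	0.04	0	5	0
Nitrendipine	0.091	-ve inotrope	0.06	0	18	0
Ranolazine	200	-ve inotrope	17	0	9	0
Tamoxifen	0.663	-ve inotrope	0.99	0	36	0
Verapamil	10	-ve inotrope	0.04	0	2	0
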