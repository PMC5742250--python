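drug	clinical_tdp	assay_call
Ajmaline	positive	positive
Astemizole	positive	negative
Azimilide	positive	positive
Bepridil	positive	positive
Chlorpromazine	positive	positive
Cisapride	positive	positive
Clarithromycin	positive	positive
Clozapine	positive	positive
D,L-Sotalol	positive	positive
Disopyramide	positive	positive
Dofetilide	positive	positive
Domperidone	positive	positive
Droperidol	positive	positive
Erythromycin	positive	positive
Flecainide	positive	positive
Ibutilide	positive	positive
Moxifloxacin	positive	positive
Ondansetron	positive	positive
Procainamide	positive	positive
Quinidine	positive	positive
Sematilide	positive	positive
Terodiline	positive	positive
Vandetanib	positive	positive
Diltiazem	negative	negative
Diphenhydramine	negative	negative
Loratadine	negative	negative
Mexiletine	negative	negative
Mibefradil	negative	negative
Nifedipine	negative	negative
Nitrendipine	negative	negative
Ranolazine	negative	negative
Tamoxifen	negative	negative
Verapamil	negative	negative
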