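icd_system,icd_code,phecode
ICD9CM,562.00,562.1
ICD9CM,562.01,562.2
ICD9CM,562.02,562.1
ICD9CM,562.03,562.2
ICD9CM,562.10,562.1
ICD9CM,562.11,562.2
ICD9CM,562.12,562.1
ICD9CM,562.13,562.2
ICD9CM,556,555.2
ICD9CM,556.9,555.2
ICD9CM,556.5,555.2
ICD9CM,558,558
ICD9CM,558.9,558
ICD9CM,560.2,560.1
ICD10CM,K57.10,562.1
ICD10CM,K57.12,562.2
ICD10CM,K57.20,562.2
ICD10CM,K57.30,562.1
ICD10CM,K57.32,562.2
ICD10CM,K57.90,562.1
ICD10CM,K57.92,562.2
ICD10CM,K51.9,555.2
ICD10CM,K51.90,555.2
ICD10CM,K52.9,558
ICD10CM,K56.2,560.1
ICD9CM,596.8,596
ICD9CM,596.59,596.5
ICD9CM,365.11,365.1
ICD9CM,253.3,253.3
ICD9CM,182.0,182
ICD10CM,N32.9,596
ICD10CM,N31.9,596.5
ICD10CM,H40.11,365.1
ICD10CM,E23.0,253.3
ICD10CM,C54.9,182
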