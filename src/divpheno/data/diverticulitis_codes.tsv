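system	code
ICD9CM	562.11
ICD9CM	562.13
ICD10CM	K57.00
ICD10CM	K57.01
ICD10CM	K57.12
ICD10CM	K57.13
ICD10CM	K57.20
ICD10CM	K57.21
ICD10CM	K57.32
ICD10CM	K57.33
ICD10CM	K57.40
ICD10CM	K57.41
ICD10CM	K57.52
ICD10CM	K57.53
ICD10CM	K57.80
ICD10CM	K57.81
ICD10CM	K57.92
ICD10CM	K57.93
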