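system	prefix
ICD9CM	556
ICD9CM	558
ICD9CM	560.2
ICD10CM	K51
ICD10CM	K52
ICD10CM	K56.2
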