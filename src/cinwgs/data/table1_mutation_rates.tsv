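group	n_cases	n_mutated
Familial Breast Cancer (FBRC)	510	84
Triple Negative Breast Cancer (TNBC)	162	16
Early Breast Cancer (EBC)	392	8
Bilateral Primary Breast Cancer (BPBC)	82	5
Male Breast Cancer (MBC)	5	0
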