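category,sex,n,mean_age,noise_pos
All,M,240,72.6,189
All,F,292,71.96,62
OlderNormal,M,12,66.46,8
OlderNormal,F,87,67.71,17
Metabolic,M,62,74.51,43
Metabolic,F,92,74.29,18
Sensory,M,101,72.32,80
Sensory,F,53,73.39,13
Unclassified,M,48,72.36,42
Unclassified,F,47,73.57,9
Unselected,M,17,72.27,14
Unselected,F,13,71.64,5
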