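category,sex,n,mean_age,noise_pos
All,F,159,64.82,0
OlderNormal,F,53,61.3,0
Metabolic,F,66,66.48,0
Sensory,F,7,68.14,0
Unclassified,F,19,67.32,0
Unselected,F,14,65.29,0
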