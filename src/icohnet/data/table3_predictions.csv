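phase,patient,actual,gp,erd,multimodal
chronic,1,31,30.34,46.07,31.45
chronic,2,56,54.23,55.46,56.02
chronic,3,44,44.16,48.66,44.09
chronic,4,52,51.73,55.16,51.96
chronic,5,32,32.58,21.08,32.03
chronic,6,40,42.85,34.44,39.98
chronic,7,54,52.79,54.36,54.01
chronic,8,48,48.74,48.35,47.99
chronic,9,45,44.82,59.28,45.04
chronic,10,59,64.99,55.21,59.14
chronic,11,63,63.44,66.70,62.99
early_chronic,1,51,41.60,50.35,44.48
early_chronic,2,66,101.50,110.40,73.95
early_chronic,3,66,59.05,61.33,75.53
early_chronic,4,36,25.57,35.85,39.70
early_chronic,5,61,67.12,61.06,60.64
early_chronic,6,55,71.09,54.89,55.40
early_chronic,7,21,18.49,20.73,22.59
early_chronic,8,46,62.93,46.52,42.28
early_chronic,9,14,21.78,14.14,12.73
early_chronic,10,66,62.88,65.71,68.59
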