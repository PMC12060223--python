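phase,patient,age,sex,affected_hand,months_after_onset,ul_fma,gs_palm,gs_pinch
chronic,1,58,M,Rt,62.8,31,1.26,0.46
chronic,2,56,F,Lt,51.3,56,3,1.9
chronic,3,49,M,Lt,49.0,44,2.3,2
chronic,4,52,F,Rt,61.8,52,3.5,1.6
chronic,5,53,M,Lt,61.6,32,0,0
chronic,6,57,M,Rt,67.3,40,3.43,1.8
chronic,7,46,F,Rt,15.9,54,3.9,2.13
chronic,8,59,M,Lt,56.5,48,4.7,5.43
chronic,9,52,M,Lt,37.3,45,2.73,5.89
chronic,10,41,M,Rt,52.9,59,5.36,3.63
chronic,11,58,M,Rt,34.3,63,5.9,5.5
early_chronic,1,54,F,Rt,3.4,51,0.89,2.27
early_chronic,2,69,M,Rt,3.87,66,2.74,6.14
early_chronic,3,31,M,Rt,3,66,6.38,12.21
early_chronic,4,52,M,Rt,3.17,36,0.63,1.75
early_chronic,5,54,M,Rt,3.37,61,1.34,4.37
early_chronic,6,66,M,Rt,2.97,55,2.39,5.55
early_chronic,7,62,F,Lt,2.97,21,1.18,1.46
early_chronic,8,60,M,Rt,3.37,46,0.37,1.32
early_chronic,9,60,M,Rt,3.8,14,0.06,0.04
early_chronic,10,55,M,Lt,3.3,66,1.94,5.03
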