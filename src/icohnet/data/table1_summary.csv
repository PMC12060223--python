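phase,column,mean,sd
chronic,age,52.82,5.67
chronic,months_after_onset,50.06,15.36
chronic,ul_fma,47.64,10.46
chronic,gs_palm,3.28,1.73
chronic,gs_pinch,2.76,2.05
early_chronic,age,56.3,10.5
early_chronic,months_after_onset,3.32,0.31
early_chronic,ul_fma,48.20,18.95
early_chronic,gs_palm,1.79,1.83
early_chronic,gs_pinch,4.01,3.54
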