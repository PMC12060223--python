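phase,model,rmse,r2,adj_r2,correlation
chronic,gp,2.24,0.96,0.95,0.9810
chronic,erd,8.15,0.61,0.57,0.7857
chronic,multimodal,0.13,0.99,0.99,0.9999
early_chronic,gp,15.1,0.70,0.67,0.8378
early_chronic,erd,14.5,0.74,0.71,0.8599
early_chronic,multimodal,4.85,0.95,0.94,0.9765
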