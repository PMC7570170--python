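parent,gca_hmf,sig_hmf,gca_hf,sig_hf
CML254,-10.06,**,-4.58,**
CML364,13.01,**,8.28,**
CML376,-0.30,,-1.45,*
CML383,-9.43,**,-4.59,**
CML435,9.26,**,6.94,**
CML442,9.48,**,1.22,
CML484,0.09,,0.58,
CML533,-12.05,**,-6.40,**
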