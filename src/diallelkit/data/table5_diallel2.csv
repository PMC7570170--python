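parent,gca_hmf,sig_hmf,gca_hf,sig_hf
CML364,14.36,**,8.61,**
CML381,-3.96,**,-1.97,*
CML383,-7.10,**,-3.77,**
CML396,2.06,*,3.97,**
CML398,-3.89,**,-2.30,**
CML451,-0.15,,-1.00,
CML510,4.89,**,0.38,
CML533,-6.22,**,-3.92,**
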