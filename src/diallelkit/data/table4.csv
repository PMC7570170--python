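component,diallel1_hmf,diallel1_hf,diallel2_hmf,diallel2_hf
sigma2_P,378.44,113.07,169.53,83.12
sigma2_A,173.39,52.12,94.85,33.59
sigma2_D,62.84,22.41,27.10,13.66
sigma2_e,133.68,36.98,43.89,33.87
gca_sca_ratio,1.38,1.16,1.75,1.23
baker_ratio,0.73,0.70,0.78,0.71
h2,0.46,0.46,0.56,0.40
H2,0.62,0.66,0.72,0.57
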