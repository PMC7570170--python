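group,group_label,parent1,parent2,hmf,hf
1,High × High,CML364,CML442,46.83,19.47
1,High × High,CML435,CML364,41.40,27.59
1,High × High,CML435,CML442,33.56,16.31
2,High × Medium,CML364,CML376,42.23,13.74
2,High × Medium,CML442,CML376,41.51,10.86
2,High × Medium,CML435,CML484,38.93,22.03
2,High × Medium,CML435,CML376,38.78,22.69
2,High × Medium,CML442,CML484,33.15,13.67
2,High × Medium,CML364,CML484,31.17,20.82
3,High × Low,CML364,CML254,32.43,15.02
3,High × Low,CML435,CML383,26.22,14.98
3,High × Low,CML364,CML383,24.22,9.91
3,High × Low,CML442,CML383,23.02,5.99
3,High × Low,CML435,CML254,19.06,9.36
3,High × Low,CML364,CML533,17.83,6.54
3,High × Low,CML442,CML254,16.25,3.87
3,High × Low,CML435,CML533,14.74,5.85
3,High × Low,CML442,CML533,11.03,2.55
4,Medium × Medium,CML484,CML376,18.86,9.98
5,Medium × Low,CML376,CML254,11.27,5.81
5,Medium × Low,CML376,CML383,27.62,5.03
5,Medium × Low,CML376,CML533,7.82,3.28
5,Medium × Low,CML484,CML254,12.97,7.71
5,Medium × Low,CML484,CML383,9.32,6.35
5,Medium × Low,CML484,CML533,12.00,5.36
6,Low × Low,CML254,CML383,11.57,4.87
6,Low × Low,CML533,CML254,12.15,4.29
6,Low × Low,CML383,CML533,13.66,4.90
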