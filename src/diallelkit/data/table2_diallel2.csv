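group,group_label,parent1,parent2,hmf,hf
1,High × High,CML364,CML510,37.61,23.83
2,High × Medium,CML364,CML396,17.61,12.82
3,High × Low,CML381,CML364,17.62,9.98
3,High × Low,CML383,CML364,11.64,9.14
3,High × Low,CML398,CML364,18.52,8.18
3,High × Low,CML451,CML364,30.32,16.22
3,High × Low,CML533,CML364,13.03,4.47
4,Medium × Medium,CML396,CML510,16.30,8.72
5,Medium × Low,CML381,CML396,21.29,14.85
5,Medium × Low,CML383,CML396,6.21,3.78
5,Medium × Low,CML398,CML396,8.56,6.20
5,Medium × Low,CML451,CML396,20.19,12.28
5,Medium × Low,CML533,CML396,12.41,9.12
5,Medium × Low,CML533,CML510,11.08,4.90
5,Medium × Low,CML381,CML510,4.00,1.67
5,Medium × Low,CML383,CML510,10.86,7.03
5,Medium × Low,CML398,CML510,14.83,5.62
5,Medium × Low,CML451,CML510,19.19,6.97
6,Low × Low,CML381,CML383,2.00,0.81
6,Low × Low,CML381,CML398,18.12,10.65
6,Low × Low,CML381,CML451,16.81,6.47
6,Low × Low,CML381,CML533,3.03,4.86
6,Low × Low,CML383,CML398,5.59,3.48
6,Low × Low,CML383,CML451,12.26,2.83
6,Low × Low,CML383,CML533,3.98,0.36
6,Low × Low,CML398,CML451,7.01,3.12
6,Low × Low,CML398,CML533,7.27,4.42
6,Low × Low,CML451,CML533,5.60,3.11
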