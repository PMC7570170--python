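parent,pedigree,adaptation,country,hmf,hf,doubling_class
CML364,SAHC1-5-1-1-5-3-B,LLT,Colombia,74.33,46.05,High
CML396,P21C5HC109-3-1-5-4-B-4-3-##-2-B*6,LLT,Mexico,22.82,21.99,Medium
CML510,SW89300-1P5S2-5-##1-6-BB,MA,Zimbabwe,29.87,9.31,Medium
CML398,P21 C5HC216-2-3-B-#*4-BBB-###-B*8,LLT,Mexico,7.01,4.24,Low
CML451,[NPH28-1*G25)*NPH28]-1-2-1-1-3-1-B*6,LLT,Mexico,8.85,4.09,Low
CML381,P501c1#-401-3-1-2-B-B,ST/MA,Mexico,3.00,1.78,Low
CML533,SA4C4HC19-3-2-2-2-3-4-3-B-B-B-B,LLT,Colombia,2.44,1.43,Low
CML383,P502c1#-771-2-2-1-1-B,ST,Mexico,0.62,0.41,Low
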