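parent,pedigree,adaptation,country,hmf,hf,doubling_class
CML364,SAHC1-5-1-1-5-3-B,LLT,Colombia,74.33,46.05,High
CML435,SA3-C4HC(16x25)-2-4-3-6-B-B-B-B-B,LLT,Colombia,65.30,36.69,High
CML442,[M37W/ZM607#bF37sr-2-3sr-6-2-X]-8-2-X-1-BBB,ST/MA,Zimbabwe,70.90,26.54,High
CML376,SLWHG-AF118-2-1-1-B-1-B-1-B-B,ST/MA,Mexico,30.23,11.76,Medium
CML484,G 19 C3H104-3-1-B-2-3-BB,ST/MA,Mexico,30.75,11.51,Medium
CML533,SA4C4HC19-3-2-2-2-3-4-3-B-B-B-B,LLT,Colombia,2.44,1.43,Low
CML383,P502c1#-771-2-2-1-1-B,ST/MA,Mexico,0.62,0.41,Low
CML254,TUXSEQ-149-2-BBB-##-1-BB-f,LLT,Mexico,0.15,0.00,Low
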