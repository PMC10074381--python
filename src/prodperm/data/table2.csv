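name,logK,logK_sd,logPerm,logPerm_sd,pair,role
cytarabine,-0.68,0.17,-13.19,0.04,cytarabine,parent
Cyt-fru,-1.35,0.05,-17.31,0.04,cytarabine,adduct
fluorouracil,0.69,0.11,-7.28,0.04,fluorouracil,parent
FU-fru,-1.13,0.06,-11.21,0.04,fluorouracil,adduct
abiraterone,5.95,0.98,-4.59,0.79,abiraterone,parent
Abi-fru,2.70,0.72,-4.00,0.61,abiraterone,adduct
paliperidone,2.95,0.43,-4.24,0.58,paliperidone,parent
Pali-fru,0.63,0.38,-6.59,0.97,paliperidone,adduct
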