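name,logK,logK_sd,logPerm,logPerm_sd,series,n_carbons
cytarabine,-0.68,0.17,-13.19,0.04,parent,0
CytO2,-1.08,0.16,-11.43,0.04,ester,2
CytO4,-1.31,0.05,-10.21,0.06,ester,4
CytO6,-0.25,0.25,-8.67,0.10,ester,6
CytO8,0.16,0.57,-7.22,0.17,ester,8
CytO10,2.08,0.60,-5.47,0.23,ester,10
CytO12,3.90,0.77,-3.55,0.45,ester,12
CytO14,5.64,0.98,-1.93,0.53,ester,14
CytO16,8.05,0.99,0.08,0.28,ester,16
CytN2,-1.15,0.26,-11.33,0.03,amide,2
CytN4,-1.35,0.04,-10.18,0.04,amide,4
CytN6,-1.37,0.04,-8.85,0.04,amide,6
CytN8,0.00,0.29,-7.42,0.05,amide,8
CytN10,1.37,0.36,-5.77,0.06,amide,10
CytC2,-0.92,0.11,-11.65,0.05,alkyl,2
CytC4,-0.27,0.13,-10.42,0.08,alkyl,4
CytC6,0.47,0.17,-8.78,0.14,alkyl,6
CytC8,1.91,0.22,-7.75,0.21,alkyl,8
CytC10,3.58,0.40,-5.48,0.42,alkyl,10
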