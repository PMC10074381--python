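# Full study set: 4 parents, 18 cytarabine chain prodrugs, 4 fructose
# adducts = 26 unique structures (cytarabine counted once).
parents: [cytarabine, abiraterone, fluorouracil, paliperidone]
series:
  - parent: cytarabine
    modification: ester
    site: O5prime
    name_pattern: "CytO{n}"
    chain_carbons: [2, 4, 6, 8, 10, 12, 14, 16]
  - parent: cytarabine
    modification: amide
    site: N4amine
    name_pattern: "CytN{n}"
    chain_carbons: [2, 4, 6, 8, 10]
  - parent: cytarabine
    modification: alkyl
    site: C5ring
    name_pattern: "CytC{n}"
    chain_carbons: [2, 4, 6, 8, 10]
adducts:
  - {parent: cytarabine, site: N4amine, name: Cyt-fru}
  - {parent: abiraterone, site: O3beta, name: Abi-fru}
  - {parent: fluorouracil, site: N1, name: FU-fru}
  - {parent: paliperidone, site: O9, name: Pali-fru}
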