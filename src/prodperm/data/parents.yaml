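# Parent APIs for the prodrug design study.
# Atom indices refer to the atom ordering of the stored SMILES as parsed.
cytarabine:
  smiles: "Nc1ccn([C@@H]2O[C@H](CO)[C@@H](O)[C@H]2O)c(=O)n1"
  sites:
    # pentose C5' primary hydroxyl -- ester / fructose attachment point
    O5prime: {kind: hydroxyl, atom_index: 9}
    # exocyclic amine on the pyrimidine ring -- amide / fructose point
    N4amine: {kind: primary-amine, atom_index: 0}
    # pyrimidine ring position 5 (aromatic CH next to the amine)
    C5ring: {kind: aromatic-CH, atom_index: 2}
abiraterone:
  smiles: "CC12CCC(O)CC1=CCC1C2CCC2(C)C1CC=C2c1cccnc1"
  sites:
    # steroid 3beta-hydroxyl
    O3beta: {kind: hydroxyl, atom_index: 5}
fluorouracil:
  smiles: "O=c1[nH]cc(F)c(=O)[nH]1"
  sites:
    # ring N1-H; amide-like nitrogen (one H replaced on condensation)
    N1: {kind: primary-amine, atom_index: 2}
paliperidone:
  smiles: "CC1=C(CCN2CCC(CC2)c2noc3cc(F)ccc23)C(=O)N2CCCC(O)C2=N1"
  sites:
    # 9-hydroxyl of the hydroxyrisperidone core
    O9: {kind: hydroxyl, atom_index: 28}
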