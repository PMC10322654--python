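# Functional groups completed into reaction centers when any member atom
# changes.  Fully user-replaceable; names are conventional, SMARTS are the
# definition.
- {name: carboxylic-acid, smarts: "[CX3](=O)[OX2H1]"}
- {name: carboxylate, smarts: "[CX3](=O)[O-]"}
- {name: ester, smarts: "[CX3](=O)[OX2H0][#6]"}
- {name: amide, smarts: "[CX3](=O)[NX3]"}
- {name: aldehyde, smarts: "[CX3H1]=O"}
- {name: ketone, smarts: "[#6][CX3](=O)[#6]"}
- {name: nitro, smarts: "[NX3+](=O)[O-]"}
- {name: nitroso, smarts: "[NX2]=O"}
- {name: nitrile, smarts: "[NX1]#[CX2]"}
- {name: amine-primary, smarts: "[NX3H2][#6]"}
- {name: hydroxyl, smarts: "[OX2H]"}
- {name: ether, smarts: "[OD2]([#6])[#6]"}
- {name: epoxide, smarts: "[OX2r3]1[#6r3][#6r3]1"}
- {name: phosphate-ester, smarts: "[PX4](=O)([OX2])([OX2])[OX2]"}
- {name: thiophosphate-ester, smarts: "[PX4](=S)([OX2])([OX2])[OX2]"}
- {name: sulfonyl, smarts: "[SX4](=O)(=O)"}
- {name: sulfoxide, smarts: "[SX3]=O"}
- {name: thiol, smarts: "[SX2H]"}
- {name: thioether, smarts: "[SX2]([#6])[#6]"}
- {name: halide-aliphatic, smarts: "[CX4][F,Cl,Br,I]"}
- {name: halide-aromatic, smarts: "[c][F,Cl,Br,I]"}
- {name: carbamate, smarts: "[NX3][CX3](=O)[OX2]"}
- {name: urea, smarts: "[NX3][CX3](=O)[NX3]"}
- {name: azo, smarts: "[NX2]=[NX2]"}
- {name: imine, smarts: "[CX3]=[NX2]"}
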