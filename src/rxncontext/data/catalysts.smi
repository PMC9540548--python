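[Pd]
O=C(/C=C/c1ccccc1)/C=C/c1ccccc1.[Pd]
CC(=O)O[Pd]OC(C)=O
Cl[Pd]Cl
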