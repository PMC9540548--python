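Cc1ccccc1
C1COCCO1
C1CCOC1
CN(C)C=O
CC(=O)N(C)C
COCCOC
CC(C)(C)O
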