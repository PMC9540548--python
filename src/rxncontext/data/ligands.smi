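c1ccc(P(c2ccccc2)c2ccccc2)cc1
C1CCC(P(C2CCCCC2)C2CCCCC2)CC1
CC(C)(C)P(C(C)(C)C)C(C)(C)C
Cc1ccccc1P(c1ccccc1C)c1ccccc1C
c1ccc(P(CCP(c2ccccc2)c2ccccc2)c2ccccc2)cc1
CC(C)c1cc(C(C)C)c(-c2ccccc2P(C2CCCCC2)C2CCCCC2)c(C(C)C)c1
CN(C)c1ccccc1-c1ccccc1P(C1CCCCC1)C1CCCCC1
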