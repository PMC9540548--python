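C=CC[Pd]Cl
Cl[Pd]c1ccccc1
CC#N.CC#N.Cl[Pd]Cl
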