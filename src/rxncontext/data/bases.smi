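CC(C)(C)[O-].[Na+]
O=C([O-])[O-].[Cs+].[Cs+]
O=P([O-])([O-])[O-].[K+].[K+].[K+]
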