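# Competitive inhibition constants of cyclosporin A against each target.
# Ki in uM; converted to ng/mL via the inhibitor molar mass (g/mol).
inhibitor: cyclosporine
molar_mass: 1202.61
ki_um:
  oatp: 0.014
  cyp3a: 2.0
  pgp: 0.895
  bcrp: 0.28
  mrp2: 4.1
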