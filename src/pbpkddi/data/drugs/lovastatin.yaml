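# Lovastatin: substrate of OATPs, MRP2 and CYP3A4.
name: lovastatin
fub: 0.03
rb: 0.57
kp:
  adipose: 298.06
  liver: 25.63
  muscle: 4.69
  lung: 9.06
  kidney: 4.25
  brain: 0.88
  heart: 11.63
  intestine: 36.2
  skin: 21.46
  spleen: 0.31
  stomach: 62.69
  rest: 0.01
clint_met_cyp3a: 6893.96
clint_uptake_oatp: 13129.8
sf_act: 4.0
clint_pd: 11569.5
peff_ab: 0.016
peff_ba:
  mrp2: 0.014
# Stored as printed; the jejunal value is inconsistent with the regional
# CYP3A-abundance rule (expected ~3448.6) and triggers a validation warning.
clint_gut:
  duodenum: 871.0
  jejunum: 89.8
  ileum: 2011.0
clint_gut_microsomal: 2.143
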