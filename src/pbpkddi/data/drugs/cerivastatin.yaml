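# Cerivastatin: substrate of OATP1B1, P-gp, BCRP, CYP3A4 and CYP2C8.
name: cerivastatin
fub: 0.017
rb: 0.76
kp:
  adipose: 0.43
  liver: 51.0
  muscle: 0.2
  lung: 1.13
  kidney: 2.93
  brain: 0.2
  heart: 2.0
  intestine: 0.2
  skin: 0.533
  spleen: 0.733
  stomach: 0.09
  rest: 0.01
clint_met_cyp3a: 979.8
clint_met_other: 1197.6
clint_uptake_oatp: 1942.8
sf_act: 12.5
clint_pd: 3541.5
clint_bile:
  pgp: 40.5
peff_ab: 0.0133
peff_ba:
  pgp: 0.0099
  bcrp: 0.0065
  mrp2: 0.0118
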