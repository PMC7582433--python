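# Fluvastatin: substrate of OATPs, P-gp, BCRP, MRP2, CYP2C9 and CYP3A4.
name: fluvastatin
fub: 0.014
rb: 0.57
kp:
  adipose: 0.339
  liver: 34.13
  muscle: 0.147
  lung: 0.407
  kidney: 1.59
  brain: 0.094
  heart: 0.82
  intestine: 8.2
  skin: 0.313
  spleen: 0.23
  stomach: 1.22
  rest: 0.01
clint_met_cyp3a: 2386.3
clint_met_other: 2801.3
clint_uptake_oatp: 9106.6
sf_act: 21.0
clint_pd: 4047.4
clint_bile:
  bcrp: 3440.0
peff_ab: 0.038
peff_ba:
  pgp: 0.035
  bcrp: 0.026
  mrp2: 0.029
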