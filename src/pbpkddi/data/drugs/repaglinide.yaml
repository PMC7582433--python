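# Repaglinide: substrate of OATP1B1, P-gp, CYP2C8 and CYP3A4.
name: repaglinide
fub: 0.011
rb: 0.62
kp:
  adipose: 0.2
  liver: 15.8
  muscle: 0.302
  lung: 0.604
  kidney: 1.48
  brain: 0.078
  heart: 0.702
  intestine: 0.07
  skin: 0.209
  spleen: 0.346
  stomach: 0.07
  rest: 0.01
clint_met_cyp3a: 2503.7
clint_met_other: 6438.0
clint_uptake_oatp: 7184.0
sf_act: 16.9
clint_pd: 4452.14
clint_bile:
  bcrp: 20.24
ka_direct: 0.04
peff_ba:
  pgp: 0.0148
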