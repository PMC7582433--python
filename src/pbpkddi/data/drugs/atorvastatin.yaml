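# Atorvastatin: substrate of OATPs, CYP3A4, P-gp, BCRP and MRP2.
name: atorvastatin
fub: 0.084
rb: 0.61
kp:
  adipose: 181.0
  liver: 4.57
  muscle: 2.64
  lung: 5.6
  kidney: 4.18
  brain: 8.44
  heart: 3.78
  intestine: 8.97
  skin: 13.16
  spleen: 2.43
  stomach: 2.64
  rest: 1.0
clint_met_cyp3a: 3469.5
clint_met_other: 612.3
clint_uptake_oatp: 6374.7
sf_act: 32.6
clint_pd: 3916.79
clint_bile:
  bcrp: 302.4
peff_ab: 0.0094
peff_ba:
  pgp: 0.0185
  bcrp: 0.0118
  mrp2: 0.011
clint_gut:
  duodenum: 12.2
  jejunum: 48.273
  ileum: 28.22
clint_gut_microsomal: 0.03
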