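# Simvastatin (modelled as the acid, parent kinetics): OATP/P-gp/CYP3A4 substrate.
name: simvastatin
fub: 0.107
rb: 0.56
kp:
  adipose: 0.39
  liver: 22.7
  muscle: 0.219
  lung: 0.426
  kidney: 2.87
  brain: 0.207
  heart: 0.612
  intestine: 20.2
  skin: 0.39
  spleen: 0.292
  stomach: 20.2
  rest: 0.01
clint_met_cyp3a: 231391.0
clint_uptake_oatp: 9234.1
sf_act: 25.0
clint_pd: 23695.5
clint_bile:
  pgp: 101.2
peff_ab: 0.01
peff_ba:
  pgp: 0.0093
clint_gut:
  duodenum: 755.2
  jejunum: 2991.3
  ileum: 1745.0
clint_gut_microsomal: 1.86
# Optional dose lag (min): time for lactone-to-acid conversion; default none.
lag_time: 0.0
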