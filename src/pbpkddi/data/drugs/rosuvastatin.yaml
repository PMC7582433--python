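# Rosuvastatin: substrate of OATPs, P-gp, BCRP and MRP2; renally secreted via BCRP.
name: rosuvastatin
fub: 0.174
rb: 0.69
kp:
  adipose: 0.82
  liver: 10.6
  muscle: 0.2
  lung: 0.4
  kidney: 1.12
  brain: 0.01
  heart: 0.4
  intestine: 0.18
  skin: 0.38
  spleen: 0.23
  stomach: 0.2
  rest: 0.01
clint_uptake_oatp: 1841.6
sf_act: 9.2
clint_pd: 242.8
clint_bile:
  bcrp: 566.6
ka_direct: 0.0022
peff_ba:
  pgp: 0.012
  bcrp: 0.013
  mrp2: 0.011
clint_gfr: 132.9
clint_sec: 420.3
sec_transporter: bcrp
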