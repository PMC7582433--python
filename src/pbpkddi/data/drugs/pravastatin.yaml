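# Pravastatin: substrate of OATPs and MRP2; renally secreted via MRP2.
name: pravastatin
fub: 0.56
rb: 0.839
kp:
  adipose: 0.14
  liver: 56.0
  muscle: 0.21
  lung: 0.36
  kidney: 48.5
  brain: 0.22
  heart: 0.32
  intestine: 0.21
  skin: 0.38
  spleen: 0.26
  stomach: 0.21
  rest: 0.11
clint_uptake_oatp: 283.3
sf_act: 19.4
clint_pd: 80.9
clint_bile:
  mrp2: 80.9
ka_direct: 0.021
# Lumen-facing MRP2 efflux clearance from enterocytes (mL/min), distributed
# over the absorptive segments by the MRP2 regional scaling factors.
clint_efflux_lumen:
  mrp2: 43.7
clint_gfr: 132.9
clint_sec: 1538.96
sec_transporter: mrp2
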