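# Bosentan: substrate of OATPs, MRP2, CYP3A4 and CYP2C9.
name: bosentan
fub: 0.02
rb: 0.6
kp:
  adipose: 0.52
  liver: 51.0
  muscle: 0.23
  lung: 1.01
  kidney: 1.14
  brain: 0.35
  heart: 0.64
  intestine: 0.47
  skin: 0.48
  spleen: 0.52
  stomach: 0.16
  rest: 0.01
clint_met_cyp3a: 1365.14
clint_uptake_oatp: 7184.0
sf_act: 1.1
clint_pd: 2023.7
clint_bile:
  pgp: 1472.6
peff_ab: 0.014
# Lumen-facing MRP2 efflux clearance (mL/min, from Vmax/Km).
clint_efflux_lumen:
  mrp2: 5.84
clren: 2.4  # observed renal clearance; secretion component resolves to 0
sec_transporter: mrp2
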