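# Cyclosporin A (CsA): perpetrator and OATP/CYP3A/P-gp substrate.
# Units: clearances mL/min, permeabilities cm/min, ka 1/min, molar mass g/mol.
name: cyclosporine
molar_mass: 1202.61
fub: 0.05
rb: 1.36
kp:  # tissue:plasma partition coefficients
  adipose: 253.35
  liver: 4.13
  muscle: 3.67
  lung: 7.75
  kidney: 5.79
  brain: 11.77
  heart: 5.22
  intestine: 5.99
  skin: 18.28
  spleen: 3.36
  stomach: 3.67
  rest: 5.24
clint_met_cyp3a: 5432.0
clint_uptake_oatp: 10857.0
sf_act: 0.1
clint_pd: 2933.0
clint_bile:
  pgp: 637.0
ka_direct: 0.025
peff_ba:
  pgp: 0.01
clint_gut:  # intestinal CYP3A intrinsic clearance per segment
  duodenum: 11.25
  jejunum: 44.6
  ileum: 25.98
clint_gut_microsomal: 0.0277  # mL/min/mg intestinal microsomal protein
clren: 3.44  # observed renal clearance; secretion component resolves to 0
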