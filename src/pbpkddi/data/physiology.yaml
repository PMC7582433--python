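# Whole-body physiology of a 70-kg adult human.
# Volumes in mL, blood flows in mL/min, GI transit rate constants in 1/min,
# intestinal radii in cm, GFR in mL/min.
cardiac_output: 5600.0
gfr: 120.0
# Fraction of total liver volume assigned to the hepatic blood sub-compartment;
# the remainder is hepatocellular water.  Tunable structural constant.
liver_blood_fraction: 0.25
tissue_volumes:
  lung: 1170.0
  kidney: 280.0
  heart: 310.0
  liver: 1690.0
  muscle: 35000.0
  skin: 7800.0
  brain: 1450.0
  adipose: 10000.0
  rob: 5100.0
  spleen: 190.0
  artery: 1730.0
  venous: 3470.0
  stomach: 160.0
  duodenum: 70.0
  jejunum: 209.0
  ileum: 139.0
  cecum: 116.0
  colon: 1116.0
tissue_flows:
  lung: 5600.0
  kidney: 1240.0
  heart: 240.0
  liver: 1518.0
  muscle: 750.0
  skin: 300.0
  brain: 700.0
  adipose: 260.0
  rob: 592.0
  spleen: 80.0
  stomach: 38.0
  duodenum: 118.0
  jejunum: 413.0
  ileum: 244.0
  cecum: 44.0
  colon: 281.0
gi_transit:
  stomach: 0.0462
  duodenum: 0.0462
  jejunum: 0.012
  ileum: 0.0058
  cecum: 0.004
  colon: 0.0013
intestinal_radii:
  duodenum: 2.0
  jejunum: 1.63
  ileum: 1.45
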