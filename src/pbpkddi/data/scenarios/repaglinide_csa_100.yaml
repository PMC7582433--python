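# Crossover design: 100 mg CsA the evening before (t=0) and the morning of
# (t=12 h); 0.25 mg repaglinide one hour after the morning CsA dose.
id: repaglinide_csa_100
victim: repaglinide
victim_regimen:
  events: [{time_h: 13, dose_mg: 0.25}]
inhibitor: cyclosporine
inhibitor_regimen:
  events: [{time_h: 0, dose_mg: 100}, {time_h: 12, dose_mg: 100}]
window_h: [13, 37]
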