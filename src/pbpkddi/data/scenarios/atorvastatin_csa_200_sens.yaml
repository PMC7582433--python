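# Sensitivity/contribution baseline: single 40 mg atorvastatin with a single
# 200 mg CsA dose given simultaneously; AUC(0-24).
id: atorvastatin_csa_200_sens
victim: atorvastatin
victim_regimen:
  events: [{time_h: 0, dose_mg: 40}]
inhibitor: cyclosporine
inhibitor_regimen:
  events: [{time_h: 0, dose_mg: 200}]
window_h: [0, 24]
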