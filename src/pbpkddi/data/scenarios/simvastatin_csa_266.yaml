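# Transplant design: single 20 mg simvastatin during chronic CsA
# 266 mg/70 kg/d twice daily; AUC(0-24) after the simvastatin dose.
id: simvastatin_csa_266
victim: simvastatin
victim_regimen:
  events: [{time_h: 168, dose_mg: 20}]
inhibitor: cyclosporine
inhibitor_regimen:
  pattern: {dose_mg: 133, interval_h: 12, n: 16}
window_h: [168, 192]
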