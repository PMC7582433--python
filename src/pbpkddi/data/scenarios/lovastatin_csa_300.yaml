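# Transplant design: 10 mg lovastatin during chronic CsA 300 mg/d twice
# daily; 24 h window after the lovastatin dose.
id: lovastatin_csa_300
victim: lovastatin
victim_regimen:
  events: [{time_h: 168, dose_mg: 10}]
inhibitor: cyclosporine
inhibitor_regimen:
  pattern: {dose_mg: 150, interval_h: 12, n: 16}
window_h: [168, 192]
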