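# Heart-transplant design: double dose (20 mg) of simvastatin during chronic
# CsA 200 mg twice daily; 24 h window after the simvastatin dose.
id: simvastatin_csa_200bid
victim: simvastatin
victim_regimen:
  events: [{time_h: 168, dose_mg: 20}]
inhibitor: cyclosporine
inhibitor_regimen:
  pattern: {dose_mg: 200, interval_h: 12, n: 16}
window_h: [168, 192]
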