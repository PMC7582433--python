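# Heart-transplant design: 10 mg rosuvastatin daily for 10 days on CsA
# 200 mg twice a day; day-10 AUC(0-24).
id: rosuvastatin_csa_200
victim: rosuvastatin
victim_regimen:
  pattern: {dose_mg: 10, interval_h: 24, n: 10}
inhibitor: cyclosporine
inhibitor_regimen:
  pattern: {dose_mg: 200, interval_h: 12, n: 20}
window_h: [216, 240]
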