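# Renal-transplant design: 20 mg fluvastatin daily for 4 weeks on CsA
# 200 mg/d twice daily; day-28 AUC(0-24).
id: fluvastatin_csa_200_20mg
victim: fluvastatin
victim_regimen:
  pattern: {dose_mg: 20, interval_h: 24, n: 28}
inhibitor: cyclosporine
inhibitor_regimen:
  pattern: {dose_mg: 100, interval_h: 12, n: 56}
window_h: [648, 672]
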