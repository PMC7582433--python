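# Renal-transplant design: 0.2 mg cerivastatin daily for 7 days on chronic
# CsA 225 mg/d twice daily; day-7 AUC(0-24).
id: cerivastatin_csa_225
victim: cerivastatin
victim_regimen:
  pattern: {dose_mg: 0.2, interval_h: 24, n: 7}
inhibitor: cyclosporine
inhibitor_regimen:
  pattern: {dose_mg: 112.5, interval_h: 12, n: 14}
window_h: [144, 168]
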