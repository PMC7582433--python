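# Renal-transplant design: 10 mg atorvastatin daily for 4 weeks on chronic
# CsA 886 mg/70 kg/d given twice daily; steady-state AUC(0-24) on day 28.
id: atorvastatin_csa_886
victim: atorvastatin
victim_regimen:
  pattern: {dose_mg: 10, interval_h: 24, n: 28}
inhibitor: cyclosporine
inhibitor_regimen:
  pattern: {dose_mg: 443, interval_h: 12, n: 56}
window_h: [648, 672]
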