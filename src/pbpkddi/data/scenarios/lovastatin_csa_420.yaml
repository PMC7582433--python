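# Kidney-allograft design: 20 mg lovastatin daily for 28 days on chronic CsA
# 420 mg/d twice daily; day-28 AUC(0-24).
id: lovastatin_csa_420
victim: lovastatin
victim_regimen:
  pattern: {dose_mg: 20, interval_h: 24, n: 28}
inhibitor: cyclosporine
inhibitor_regimen:
  pattern: {dose_mg: 210, interval_h: 12, n: 56}
window_h: [648, 672]
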