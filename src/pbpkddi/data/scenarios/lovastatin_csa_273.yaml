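# Heart-transplant design: 10 mg lovastatin daily for 10 days on chronic CsA
# 273 mg/d twice daily; day-10 AUC(0-8).
id: lovastatin_csa_273
victim: lovastatin
victim_regimen:
  pattern: {dose_mg: 10, interval_h: 24, n: 10}
inhibitor: cyclosporine
inhibitor_regimen:
  pattern: {dose_mg: 136.5, interval_h: 12, n: 20}
window_h: [216, 224]
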