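# Heart-transplant design: 10 mg pravastatin daily to day 29 on chronic CsA
# 400 mg/d twice daily; day-29 AUC(0-24).
id: pravastatin_csa_400
victim: pravastatin
victim_regimen:
  pattern: {dose_mg: 10, interval_h: 24, n: 29}
inhibitor: cyclosporine
inhibitor_regimen:
  pattern: {dose_mg: 200, interval_h: 12, n: 58}
window_h: [672, 696]
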