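# Healthy-subject design: bosentan 500 mg twice daily for 8 days; CsA 300 mg
# twice daily from the day-1 evening; day-8 morning-dose AUC(0-12).
id: bosentan_csa_300
victim: bosentan
victim_regimen:
  pattern: {dose_mg: 500, interval_h: 12, n: 16}
inhibitor: cyclosporine
inhibitor_regimen:
  pattern: {dose_mg: 300, interval_h: 12, n: 15, start_h: 12}
window_h: [168, 180]
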