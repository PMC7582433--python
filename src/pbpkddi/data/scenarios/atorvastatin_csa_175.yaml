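# Crossover design: 40 mg atorvastatin daily for 7 days; CsA 175 mg/70 kg on
# the evening of day 6 and with the day-7 morning dose; AUC(0-6) on day 7.
id: atorvastatin_csa_175
victim: atorvastatin
victim_regimen:
  pattern: {dose_mg: 40, interval_h: 24, n: 7}
inhibitor: cyclosporine
inhibitor_regimen:
  events: [{time_h: 132, dose_mg: 175}, {time_h: 144, dose_mg: 175}]
window_h: [144, 150]
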