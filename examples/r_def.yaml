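# Defined-Ca2+ calibration solution (totals in mM)
compounds:
  KCl: 129.5
  KOH: 13.0
  NaCl: 10.3
  NaOH: 4.7
  MgCl2: 1.0
  HEPES: 5.0
  EGTA: 4.0
  CaCl2: 2.7
  fura-2: 0.05
pH: 7.2
temperature_C: 22.0
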