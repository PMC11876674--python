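# HBCx-9 study-1-style arm definitions for the command-line interface.
tumour: {t_doub: 27, def4: 0.2, v0: 100}
horizon_days: 42
arms:
  vehicle: {}
  rucaparib_50_qd:
    rucaparib: "50 mg/kg qd x35d"
  gartisertib_3_qd:
    gartisertib: "3 mg/kg qd x35d"
  combo_qd:
    rucaparib: "50 mg/kg qd x35d"
    gartisertib: "3 mg/kg qd x35d"
  combo_intermittent:
    rucaparib: "50 mg/kg qd x35d"
    gartisertib: "3 mg/kg (1won/1woff)x2 + 1won"
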