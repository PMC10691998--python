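checksum: 3e552216a8c5dcea
flags:
  ikkb_deactivation_enabled: true
nominal_totals:
  CAR: 1.0
  IKKb: 6.0
  IkBa: 1.0
  NFkB: 1.0
  RIP1: 1.0
  TAK1: 1.0
  TRAF2: 1.0
rates:
  k_ass: 27.771
  k_bdeg: 0.00974371
  k_bind: 0.0152222
  k_cdeg: 0.000550824
  k_deact: 1.49313
  k_deg: 0.0213898
  k_degc: 1.24299
  k_exp: 0.306381
  k_ikk: 1591.87
  k_in: 0.010452
  k_rip: 5.0
  k_ripr: 0.381041
  k_sdeg: 1.2124
  k_sig: 11.213
  k_sigr: 0.00133144
  k_syn: 0.36391
  k_syn0: 6.40597e-05
  k_tak: 5.0
  k_takr: 0.5
  k_unbind: 67.4577
schema_version: 1
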