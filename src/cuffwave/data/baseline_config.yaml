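heart:
  T: 0.8
  Emin: 10670000.0
  Emax: 260000000.0
  tm: 0.32
  V0: 1.0e-05
  Vlv: 0.000125
  pla: 1066.6
  Rlv: 400000.0
  Llv: 6670.0
  Rla: 600000.0
  Lla: 6670.0
  Vb: 2.0e-06
blood:
  density: 1050.0
  viscosity: 0.0035
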