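# Y512A-like rate set: the I1 -> I2 transition during acidic exposure is
# faster than the shortest practical exposure (tau 20 ms), so no ~10 ms
# recovery component is observed; I2 <-> I3 equilibrate on the same fast
# scale, so the component fractions show no exposure-duration dependence.
# Illustrative fixture, not fitted parameters.
states:
  - {name: O, conducting: true}
  - {name: I1, conducting: false}
  - {name: I2, conducting: false}
  - {name: I3, conducting: false}
edges:
  - {from: O,  to: I1, rate_key: k_o_i1}
  - {from: I1, to: O,  rate_key: k_i1_o}
  - {from: I1, to: I2, rate_key: k_i1_i2}
  - {from: I2, to: I1, rate_key: k_i2_i1}
  - {from: I2, to: I3, rate_key: k_i2_i3}
  - {from: I3, to: I2, rate_key: k_i3_i2}
rates:
  pH7.4:
    k_o_i1: 0.0
    k_i1_o: 0.1
    k_i1_i2: 0.0
    k_i2_i1: 0.01
    k_i2_i3: 0.0
    k_i3_i2: 0.001
  pH5:
    k_o_i1: 0.12
    k_i1_o: 0.0
    k_i1_i2: 0.1       # I1 empties with tau 10 ms, complete well before 50 ms
    k_i2_i1: 0.0
    k_i2_i3: 0.05      # I2 <-> I3 equilibrate before the shortest exposure
    k_i3_i2: 0.05
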