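# E166Q-like rate set: recovery dominated by the ~10 ms component with a
# smaller ~100 ms component; channels barely deepen past I1 during acidic
# exposure, so the component fractions show no exposure-duration dependence.
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
    k_o_i1: 0.1
    k_i1_o: 0.0
    k_i1_i2: 0.0002   # very slow deepening: I1 retains occupancy
    k_i2_i1: 0.01     # backward transition keeps I2 nearly empty
    k_i2_i3: 0.0
    k_i3_i2: 0.0
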