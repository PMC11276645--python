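# E166A-like rate set: recovery dominated by the ~100 and ~1000 ms
# components (no ~10 ms component), fractions independent of acidic-exposure
# duration.  Illustrative fixture, not fitted parameters.
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
    k_o_i1: 0.1       # stronger inhibition than C212S/Y512A
    k_i1_o: 0.0
    k_i1_i2: 0.05     # sub-50-ms I1 -> I2
    k_i2_i1: 0.0
    k_i2_i3: 0.04     # fast I2 <-> I3 equilibration: fractions exposure-flat
    k_i3_i2: 0.04
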