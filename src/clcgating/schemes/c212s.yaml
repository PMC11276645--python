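# C212S-like rate set on the four-state chain: all three recovery components
# (10/100/1000 ms) present, and a slowed I1 -> I2 transition during acidic
# exposure (time constant ~370 ms), so the fast recovery fraction decays with
# acidic-exposure duration.  Illustrative fixture, not fitted parameters.
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
    k_o_i1: 0.08
    k_i1_o: 0.0
    k_i1_i2: 0.0027027   # 1/370 ms^-1
    k_i2_i1: 0.0
    k_i2_i3: 0.002
    k_i3_i2: 0.0
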