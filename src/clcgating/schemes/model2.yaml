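# Four-state slow-gating chain O - I1 - I2 - I3: one conducting open state
# and three progressively deeper nonconducting inactivated states.  The
# neutral-pH (recovery) rate set is calibrated so the three relaxation time
# constants sit at the 10 / 100 / 1000 ms reference scales; values are
# illustrative fixtures, not fitted parameters.
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
    k_i1_o: 0.1        # tau ~10 ms
    k_i1_i2: 0.0
    k_i2_i1: 0.01      # tau ~100 ms
    k_i2_i3: 0.0
    k_i3_i2: 0.001     # tau ~1000 ms
  pH5:
    k_o_i1: 0.08       # inhibition tau ~12.5 ms
    k_i1_o: 0.0
    k_i1_i2: 0.0027027 # I1 -> I2 deepening, tau ~370 ms
    k_i2_i1: 0.0
    k_i2_i3: 0.002
    k_i3_i2: 0.0
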