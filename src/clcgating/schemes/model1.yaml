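# Three-state slow-gating scheme: open <-> inhibited <-> inactivated.
# Rates (1/ms) are illustrative calibration values, not fitted parameters:
# recovery from the inhibited state near the ~2000 ms wild-type scale at
# -40 mV, with a deeper inactivated state recovered an order of magnitude
# more slowly.
states:
  - {name: O, conducting: true}
  - {name: inhibited, conducting: false}
  - {name: inactivated, conducting: false}
edges:
  - {from: O, to: inhibited, rate_key: k_close}
  - {from: inhibited, to: O, rate_key: k_open}
  - {from: inhibited, to: inactivated, rate_key: k_deepen}
  - {from: inactivated, to: inhibited, rate_key: k_return}
rates:
  pH7.4:
    k_close: 0.0
    k_open: 0.0005      # tau ~2000 ms
    k_deepen: 0.0
    k_return: 0.00005   # tau ~20000 ms
  pH5:
    k_close: 0.02       # inhibition tau ~50 ms
    k_open: 0.0
    k_deepen: 0.001
    k_return: 0.0
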