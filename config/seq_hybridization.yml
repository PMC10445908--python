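# Per-cycle hybridization: the 'probe' product is bound to the cycle's probe
# and picked up from its tray slot by the pipetting-robot needle.
name: hybridization
steps:
  - {product: probe, valve: 5, volume_ul: 1000.0, flow_ul_min: 200.0, incubation_s: 600.0}
  - {product: wash-buffer, valve: 1, volume_ul: 1500.0, flow_ul_min: 300.0, incubation_s: 0.0}
  - {product: imaging-buffer, valve: 4, volume_ul: 800.0, flow_ul_min: 250.0, incubation_s: 60.0}
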