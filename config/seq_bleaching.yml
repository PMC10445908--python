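# Chemical bleaching between cycles.
name: bleaching
steps:
  - {product: bleach-solution, valve: 6, volume_ul: 1000.0, flow_ul_min: 250.0, incubation_s: 300.0}
  - {product: wash-buffer, valve: 1, volume_ul: 1500.0, flow_ul_min: 300.0, incubation_s: 0.0}
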