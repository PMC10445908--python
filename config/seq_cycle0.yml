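# Cycle-0 chemistry: nuclear stain + fiducial probe, then imaging buffer.
name: cycle-0
steps:
  - {product: DAPI-stain, valve: 2, volume_ul: 500.0, flow_ul_min: 200.0, incubation_s: 120.0}
  - {product: fiducial-probe, valve: 3, volume_ul: 800.0, flow_ul_min: 250.0, incubation_s: 300.0}
  - {product: wash-buffer, valve: 1, volume_ul: 1000.0, flow_ul_min: 300.0, incubation_s: 0.0}
  - {product: imaging-buffer, valve: 4, volume_ul: 800.0, flow_ul_min: 250.0, incubation_s: 60.0}
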