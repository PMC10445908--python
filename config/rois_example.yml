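- {id: '001', x_um: 0.0, y_um: 0.0}
- {id: '002', x_um: 90.0, y_um: 0.0}
- {id: '003', x_um: 90.0, y_um: 90.0}
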