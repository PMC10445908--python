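# A small complete Hi-M experiment (paths relative to the repository root).
task: him_full
sample_name: embryo-01
save_root: scratch/run
imaging:
  exposure_ms: 50.0
  channels: [[561, 20.0], [640, 30.0]]
  n_planes: 60
  dz_nm: 250.0
  z_start_um: 48.5
  save_format: tiff
roi_file: config/rois_example.yml
sequences:
  cycle0: config/seq_cycle0.yml
  hybridization: config/seq_hybridization.yml
  bleaching: config/seq_bleaching.yml
probes:
  - {cycle: 1, name: RT01, tray_slot: [1, 1, 1]}
  - {cycle: 2, name: RT02, tray_slot: [1, 2, 1]}
n_cycles: 2
seed: 0
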