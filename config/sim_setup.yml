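# Example setup: a fully simulated rig.
devices:
  clk: {model: clock.sim}
  cam: {model: camera.sim.ixon512}
  ls: {model: lasers.sim}
  fw: {model: filterwheel.sim}
  st: {model: stage.sim.xy}
  pz: {model: piezo.sim.pifoc}
  qpd: {model: qpd.sim}
  flu: {model: fluidics.sim}
logic:
  acq: {logic: acquisition, connect: {camera: cam, piezo: pz, lasers: ls, stage: st}}
  focus: {logic: focus, connect: {qpd: qpd, piezo: pz, lasers: ls}}
  fluidics: {logic: fluidics, connect: {plant: flu}}
  roi: {logic: roi, connect: {stage: st}}
global:
  field_um: 200.0
  pixel_um: 0.16
  seed: 0
  sample:
    n_emitters: 120
    n_probes: 3
    drift_rate_nm_s: 2.0
    diffusion_nm2_s: 1.0
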