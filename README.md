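# himscope

Headless control framework for **multiplexed sequential imaging (Hi-M)**
experiments, backed by physically modeled hardware simulators.

Hi-M (and related sequential/multiplexed FISH methods) images the same
sample regions over tens of hybridization / imaging / chemical-bleaching
cycles, coordinating a widefield microscope with a microfluidics rig for
days of unattended operation. The software problem is orchestration:
autofocus that survives thermal drift, injections delivered at controlled
flow rates and volumes, stage mosaics over many regions of interest (ROIs),
synchronized multicolor z-stacks, and disciplined stop/pause behavior.

`himscope` implements that orchestration layer for developers and
instrument builders, with every hardware class behind an abstract interface
and *simulated* implementations driven by a virtual clock — so a multi-hour
experiment (settle times, incubations, drift included) runs in seconds on a
laptop, deterministically, from a single seed.

## What is modeled

- **Camera** — Gaussian point-spread function with defocus broadening
  σ(dz) = σ₀·√(1 + (dz/z_R)²), Poisson photon statistics, Gaussian read
  noise, constant offset; 16-bit output.
- **Autofocus sensor** — a quadrant photodiode (QPD) reading the reflection
  of a 785 nm infrared laser, linear in the objective–sample distance.
  Calibration runs a 2 µm axial ramp, fits V vs z, and is *valid* only when
  the response is monotonic with precision (RMS fit residual / |slope|)
  below 30 nm. A positional-form PID then locks focus or re-finds it per
  ROI, defining each stack's reference position 1–2 µm below the focal
  plane.
- **Fluidics** — valve positioner, pipetting-robot needle, pressure pump
  and flow sensor over a first-order plant (flow → k·pressure, τ = 2 s).
  Injection steps (product, valve, volume, flow rate, incubation) are
  delivered under PID flow control with volume-triggered advancement;
  typical steps are 1–2 ml at 150–300 µl/min.
- **Stage/piezo** — XY travel ±10 mm, z-piezo 0–100 µm, settle times on the
  virtual clock; snake-ordered mosaics and region interpolation cover large
  sample areas with parametrized tile overlap.
- **Acquisition** — multicolor z-stacks (defaults: 60 planes, 250 nm
  spacing, 50 ms exposure) with per-plane channel interleaving and a strict
  synchronization contract: exactly one laser on during each exposure,
  piezo settled at every trigger. Stacks are written as TIFF, FITS or raw
  arrays plus a YAML metadata sidecar, named
  `scan_SSS_PROBE_RRR_ROI_chCC.tif`.
- **Task engine** — a table-driven state machine (stopped, starting,
  running, pausing, paused, resuming, finishing) runs the full experiment:
  cycle 0 (nuclear stain + fiducials, reference stacks) then n cycles of
  hybridize → image all ROIs → bleach, with smooth (end-of-cycle) and
  emergency stops, a busy arbiter, an atomically-replaced YAML status file
  for external trackers, and per-stack pre-analysis (variance sharpness,
  best-focus plane, max projection).

## Worked example

Run a complete 2-cycle simulated experiment from the shipped configs:

```bash
himscope run --setup config/sim_setup.yml --config config/experiment_him.yml
```

prints

```
task completed: 2 cycle(s), 18 image file(s)
```

— 18 files are 12 cycle images (2 cycles × 3 ROIs × 2 channels) plus the
6-image cycle-0 reference set, under `scratch/run/` with one metadata
sidecar per stack. About 6 000 s of virtual experiment time elapse in ~15 s
of wall time. Inspect the live status file (or poll it during a run):

```bash
himscope status --watch scratch/run/status.yml
```

```
task_state: stopped
cycle: 2
roi_id: '003'
fluidics_step: bleaching
fluidics_delivered_ul: 2500.69929844539
preanalysis:
  best_focus_plane: 8
  file_stem: scan_002_RT02_003_ROI
```

The fluidics total is the bleaching sequence's delivered volume
(1000 + 1500 µl within the PID's ~0.1 % volume-trigger overshoot), and the
pre-analysis names the sharpest plane of the last stack. The same Python
API is available directly (`himscope.load_setup`, `TaskRunner`,
`build_mosaic`, …); see `docs/methods.md` for the models and their
parameters.

Other commands: `himscope validate --config …`,
`himscope plan-mosaic --center 0,0 --rows 3 --cols 3 --fov 100
--overlap 0.1 -o rois.yml`.

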