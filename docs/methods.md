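# Methods

This note documents the models behind `himscope`'s simulated hardware, the
control algorithms, the parameters that matter, and the limits of what the
simulation can demonstrate about real instruments.

## Virtual time and randomness

All timed behavior — stage settling, camera exposures, valve moves,
incubations, sample drift — consumes *virtual* seconds on a shared
`SimClock`. Devices with time-dependent state (the sample's focal surface,
the fluidics plant) subscribe to the clock and are stepped on every
advance, so a 10-minute incubation is one O(1) call. Consequently a
multi-hour experiment executes in seconds and the event ordering is exactly
what a real-time run would produce.

Randomness comes from one root seed. Each device draws from an independent
substream keyed by `(seed, crc32(role name))`, so adding, removing or
reordering devices never perturbs another device's noise, and any fixed
call sequence is bit-reproducible. The task engine inherits this: a
completed run's pixel data, metadata and status-file sequence are identical
across repeats with the same seed.

## Virtual sample

The specimen is a set of point emitters at fixed lateral positions with
axial offsets relative to a focal surface `surface_z`. Per advance of dt
seconds the surface moves by `rate·dt` plus a Gaussian random-walk
increment of variance `diffusion·dt` (defaults in the shipped setup:
2 nm/s and 1 nm²/s — slow thermal drift). Each emitter belongs to exactly
one hybridization probe and is visible at the readout line (640 nm) only
while that probe is hybridized; a configurable fraction are additionally
fiducials, visible at 561 nm in every cycle; after the cycle-0 nuclear
stain, all emitters respond at 405 nm. Hybridization and bleaching are
instantaneous state flips triggered by the task engine around the
corresponding injection sequences — the chemistry kinetics themselves are
not modeled.

## Image formation

Expected counts per pixel are
`offset + gain · photons`, where each visible emitter contributes an
isotropic 2-D Gaussian of total weight
`brightness (photons/ms) · exposure (ms) · intensity/100` and width

    sigma(dz) = sigma0 · sqrt(1 + (dz / z_R)^2),
    dz = piezo_z − (surface_z + emitter_z)

with defaults σ₀ = 1.3 px and z_R = 0.4 µm. Gaussians are truncated at
±4σ and renormalized over the window, so the photon budget is conserved
exactly in expectation (the photon-budget tests rely on this). Sampled
frames are `offset + gain·Poisson(photons) + N(0, read_noise)`, rounded
and clipped to 16 bits. This is deliberately a Gaussian-PSF-level model:
no aberrations, no vignetting, no pixel-response nonuniformity — adequate
for exercising synchronization, focus logic and file plumbing, not for
validating deconvolution or PSF fitting downstream.

## Autofocus

The QPD signal is `gain·(piezo_z − surface_z) + offset + N(0, noise)`,
valid only while the 785 nm laser is on (defaults: 0.5 V/µm, 0.005 V RMS
noise — a 10 nm-equivalent floor). Real QPD responses are linear only near
focus; the simulation is globally linear, so calibration-range effects are
not represented.

**Calibration** steps the piezo over a 2 µm ramp (21 steps, centered on the
current position, upward) and fits signal vs z by least squares.
*Precision* is defined as the RMS fit residual divided by |slope|,
expressed in nm — the most direct length-equivalent of the ramp's voltage
scatter; repeatability-of-setpoint was a plausible alternative reading and
is noted as such. Validity is exactly `monotonic AND precision < 30 nm`,
monotonicity meaning all consecutive signal differences share one sign.
With a 10 nm noise floor the expected precision is ≈ 9.5 nm
(σ·√(19/21)), comfortably inside the bound; the acceptance script
reproduces this number.

**PID** (shared by focus and flow control) is discrete positional form with
clamped-integral anti-windup: the integral update is tentatively applied,
and if the resulting output saturates, the output is clamped and the
integral reverts. Focus gains default to kp = 0.6, ki = 0.2 s⁻¹, kd = 0 at
a 100 ms loop period — conservative values that are stable for the
simulated plant over a wide drift range; no tuning claim is made for any
real stage. The focus lock clamps every commanded position to the piezo
travel (0–100 µm).

**Per-ROI focus search** returns the piezo to the stored QPD setpoint using
averaged readings (8 per iteration, ≤6 iterations, 2 nm convergence
threshold) and defines the stack reference `focal_z − below_offset` with
`below_offset` defaulting to 1.5 µm (the 1–2 µm convention that guarantees
full axial coverage of the sample).

## Fluidics

The pump plant is first-order linear: flow relaxes toward
`k_flow · pressure` with time constant τ (defaults 1.25 µl·min⁻¹·mbar⁻¹,
2 s) — the simplest plant for which PID tuning is meaningful. The update is
the exact exponential step, sub-stepped at ≤0.25 s so the trapezoidal
volume integral stays accurate across large clock advances. The flow
sensor adds Gaussian noise (2 µl/min RMS); the integrated volume uses the
true flow.

Injection steps run a PI loop (kp = 0.8 mbar per µl/min, ki = 0.5 s⁻¹,
100 ms period, output clamped to 0–1000 mbar) on the measured flow and stop
within one control tick of the integrated volume reaching target; the
reported *delivered* volume is taken at that trigger instant, so overshoot
is bounded by one tick of flow. After pump-off the plant drains (≈5τ)
before any incubation window is counted, which keeps incubations genuinely
flow-free. A step whose flow stays below 10 % of target for 30 s of virtual
time is reported as a fault (blocked line) with the pump commanded off.
Steps execute strictly sequentially; incubation never overlaps imaging of
other ROIs — overlapping them is a real-instrument optimization this
implementation deliberately omits.

## ROI planning

Mosaics place `rows × cols` square tiles at pitch `fov·(1 − overlap)`
centered on a given position, visited in boustrophedon order starting at
the minimal-x, minimal-y tile moving toward +x (the starting corner is a
convention, chosen once). Region interpolation computes per-axis tile
counts by `max(1, ceil((span − fov)/pitch) + 1)` and centers the grid on
the region, splitting the slack between both edges; coverage is
property-tested against a 1 µm raster oracle. "Number of tiles" is read as
rows × cols rather than a total count. IDs are 3-digit zero-padded in visit
order, matching the filename convention.

## Acquisition and files

Stack plans enumerate (plane, channel) pairs plane-major: all channels are
exposed at each z before the piezo steps, minimizing axial drift between
channels of one plane (the alternative — one full z-pass per channel — was
rejected for that reason). The executor enforces, and the event log lets
tests audit, the synchronization contract: piezo settled at every trigger,
exactly one visible laser on during each exposure, all lasers off across
moves, z nondecreasing.

One file per channel is written (multipage along z, 16-bit) in TIFF (via
`tifffile`), FITS (a minimal single-HDU writer: BITPIX 16 with
BZERO = 32768 for unsigned data) or raw little-endian binary with a YAML
shape header, plus a `<stem>_meta.yml` sidecar carrying sample name,
exposure, laser lines and intensities, autofocus parameters (setpoint,
gains, calibration slope and precision), stage XY, scan step and total z
range. Filenames are `scan_SSS_PROBE_RRR_ROI_chCC.ext`; the parser also
accepts extra underscore tokens before `chCC` (e.g. `converted_decon`)
that downstream processing inserts, while the writer never emits them. The
scan ordinal carries the cycle number (cycle 0 = `scan_000`) and the probe
token the cycle label; both are recorded so either convention can be
consumed.

## Task engine

The state machine is table-driven over
stopped/starting/running/pausing/paused/resuming/finishing. `finishing`
carries the smooth-stop semantics — *complete the current cycle, then
stop* — so a smooth stop is an ordinary table transition from running,
pausing or paused; emergency stop is legal from every non-stopped state and
reaches stopped in one transition after safe-state actions (all lasers
0 %, IR off, pump 0 mbar, valve left in place). Pause is honored at ROI
boundaries and a resumed run restarts from the next ROI. While a task owns
the rig, a busy arbiter rejects hardware commands from other entry points.

Status snapshots (virtual timestamp, task state, cycle, ROI, fluidics step
with flow and delivered volume, last pre-analysis summary) are written via
write-temp-and-rename, so a polling consumer can read the file at any
instant and always parse a complete document. Pre-analysis computes
per-plane intensity variance as the sharpness trace (argmax = best-focus
plane, ties to the lowest index) and the per-pixel maximum projection —
a deliberately simple pair sufficient for remote monitoring.

## Problem sizes used in tests

The test and acceptance suites run a 64 × 64-pixel camera, 3 ROIs, 2
channels, 5 planes and 20 µl injection steps — chosen so a full two-cycle
experiment, including two deliveries per chemistry block and all settle
and incubation time, completes in well under a second while exercising
every code path at the default operating parameters (2 µm / 21-step
calibration, 250 nm plane spacing, 50 ms exposure, 250 µl/min flow). The
shipped example configs use a 512 × 512 camera and millilitre-scale
injections for a more realistic demonstration.

## Known limitations

- Only the QPD autofocus modality is modeled; camera-based sharpness
  autofocus is out of scope.
- No optical rigor beyond the Gaussian PSF; no temperature, vibration or
  stage-repeatability error models.
- The fluidics plant is a single pressure-driven channel; multi-pump
  coordination and syringe-pump dynamics are not represented.
- Passing tests demonstrate correctness of the *control logic and file
  contracts* under the simulated physics, not performance of any real
  microscope; real drivers implementing the abstract interfaces are the
  intended substitution point.
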