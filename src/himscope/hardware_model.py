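"""Simulated microscope and fluidics hardware behind abstract interfaces.

Every simulated device is driven by a shared :class:`SimClock`, so settle
times, incubations and sample drift elapse in *virtual* seconds: a multi-hour
multiplexed acquisition runs in seconds of wall time while preserving the
temporal ordering that the control logic depends on.

The physical models are deliberately simple but quantitative:

* camera — Gaussian point-spread function whose width grows with defocus as
  ``sigma(dz) = sigma0 * sqrt(1 + (dz/z_R)^2)``, Poisson photon statistics,
  Gaussian read noise and a constant offset;
* infrared autofocus sensor (quadrant photodiode) — signal linear in the
  objective–sample distance, gated on the 785 nm laser;
* pump/flow plant — first-order linear system, ``flow`` relaxing toward
  ``k_flow * pressure`` with time constant ``tau``;
* sample — point emitters on a focal surface that drifts linearly and by a
  random walk, with per-cycle visibility driven by probe hybridization.

Randomness: one root seed; every device draws from an independent substream
keyed by its role name, so adding or re-ordering devices never perturbs
another device's noise.
"""

from __future__ import annotations

import zlib
from abc import ABC, abstractmethod
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = [
    "HardwareError",
    "TravelError",
    "SimClock",
    "substream",
    "VirtualSample",
    "generate_sample",
    "StageState",
    "LaserBank",
    "CameraSettings",
    "QPDReading",
    "FluidicsHardwareState",
    "CameraInterface",
    "LightSourceInterface",
    "FilterWheelInterface",
    "XYStageInterface",
    "ZPiezoInterface",
    "AutofocusSensorInterface",
    "ValveInterface",
    "PumpInterface",
    "FlowSensorInterface",
    "NeedlePositionerInterface",
    "FluidicsPlantInterface",
    "SimulatedCamera",
    "SimulatedLaserBank",
    "SimulatedFilterWheel",
    "SimulatedXYStage",
    "SimulatedPiezo",
    "SimulatedQPD",
    "SimulatedFluidics",
    "render_frame",
    "expected_image",
    "read_qpd",
    "step_fluidics",
    "VISIBLE_LINES_NM",
]

VISIBLE_LINES_NM = (405, 488, 561, 640)

XY_TRAVEL_UM = 10_000.0
PIEZO_TRAVEL_UM = (0.0, 100.0)


class HardwareError(RuntimeError):
    """A device was commanded in a state that a real instrument would refuse."""


class TravelError(HardwareError):
    """A motion target outside the device travel range."""


def substream(root_seed: int, name: str) -> np.random.Generator:
    """Independent random substream keyed by ``name`` under one root seed."""
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(root_seed), key]))


# ---------------------------------------------------------------------------
# Virtual clock
# ---------------------------------------------------------------------------


class SimClock:
    """Monotone virtual time source.

    Devices with time-dependent state (sample drift, the fluidics plant)
    subscribe to the clock and are stepped on every :meth:`advance`, so a
    single call site controls the passage of time for the whole rig. All
    waits are O(1) in wall-clock time regardless of ``dt``.
    """

    def __init__(self) -> None:
        self.now: float = 0.0
        self._subscribers: list[Callable[[float], None]] = []

    def subscribe(self, callback: Callable[[float], None]) -> None:
        self._subscribers.append(callback)

    def advance(self, dt_s: float) -> None:
        if dt_s < 0:
            raise ValueError(f"cannot advance the clock by a negative dt ({dt_s} s)")
        if dt_s == 0:
            return
        self.now += dt_s
        for callback in self._subscribers:
            callback(dt_s)


# ---------------------------------------------------------------------------
# Virtual sample
# ---------------------------------------------------------------------------


@dataclass
class VirtualSample:
    """Seeded synthetic specimen observed by every simulated sensor.

    Emitters live at fixed lateral positions with axial offsets relative to a
    focal surface ``surface_z_um`` that drifts over time. Each emitter belongs
    to exactly one hybridization probe (visible at the readout line only while
    that probe is hybridized); a subset are additionally fiducials, visible at
    the fiducial line in every cycle; after nuclear staining all emitters are
    visible at the stain line.
    """

    x_um: np.ndarray
    y_um: np.ndarray
    z_um: np.ndarray  # axial offset relative to the focal surface
    brightness: np.ndarray  # photons/ms at 100 % laser intensity
    probe: np.ndarray  # probe name per emitter (object array of str)
    is_fiducial: np.ndarray  # bool
    probe_names: tuple[str, ...]
    field_um: float
    surface_z_um: float
    drift_rate_nm_s: float
    diffusion_nm2_s: float
    seed: int
    readout_line_nm: int = 640
    fiducial_line_nm: int = 561
    stain_line_nm: int = 405
    hybridized: set = field(default_factory=set)
    stained: bool = False
    _rng: np.random.Generator | None = None

    def __post_init__(self) -> None:
        if self._rng is None:
            self._rng = substream(self.seed, "sample-drift")

    @property
    def n_emitters(self) -> int:
        return int(self.x_um.size)

    # -- chemistry ----------------------------------------------------------
    def hybridize(self, probe_name: str) -> None:
        if probe_name not in self.probe_names:
            raise KeyError(f"unknown probe {probe_name!r}")
        self.hybridized.add(probe_name)

    def bleach(self) -> None:
        """Chemical bleaching removes all hybridized readout signal."""
        self.hybridized.clear()

    def stain(self) -> None:
        self.stained = True

    # -- time ---------------------------------------------------------------
    def advance(self, dt_s: float) -> None:
        """Drift the focal surface; called from the clock subscription."""
        if dt_s < 0:
            raise ValueError("negative dt")
        if dt_s == 0:
            return
        step_um = self.drift_rate_nm_s * dt_s * 1e-3
        if self.diffusion_nm2_s > 0:
            step_um += self._rng.normal(0.0, np.sqrt(self.diffusion_nm2_s * dt_s)) * 1e-3
        self.surface_z_um += step_um

    # -- optics -------------------------------------------------------------
    def visible_mask(self, line_nm: int) -> np.ndarray:
        """Boolean mask of emitters emitting under excitation ``line_nm``."""
        if line_nm == self.fiducial_line_nm:
            return self.is_fiducial.copy()
        if line_nm == self.stain_line_nm:
            if self.stained:
                return np.ones(self.n_emitters, dtype=bool)
            return np.zeros(self.n_emitters, dtype=bool)
        if line_nm == self.readout_line_nm:
            if not self.hybridized:
                return np.zeros(self.n_emitters, dtype=bool)
            return np.isin(self.probe, sorted(self.hybridized))
        return np.zeros(self.n_emitters, dtype=bool)


def generate_sample(
    n_emitters: int,
    field_um: float = 200.0,
    n_probes: int = 3,
    drift_rate_nm_s: float = 0.0,
    diffusion_nm2_s: float = 0.0,
    seed: int = 0,
    fiducial_fraction: float = 0.5,
    brightness_mean: float = 150.0,
    z_spread_um: float = 0.6,
    surface_z_um: float = 50.0,
) -> VirtualSample:
    """Draw a reproducible virtual specimen.

    Each emitter is assigned to exactly one probe; a ``fiducial_fraction``
    subset is additionally tagged fiducial. Identical arguments (including
    the seed) give field-by-field identical samples.
    """
    if n_emitters < 0:
        raise ValueError("n_emitters must be >= 0")
    if n_probes < 1:
        raise ValueError("n_probes must be >= 1")
    rng = substream(seed, "sample-geometry")
    probe_names = tuple(f"RT{i + 1:02d}" for i in range(n_probes))
    x = rng.uniform(0.0, field_um, n_emitters)
    y = rng.uniform(0.0, field_um, n_emitters)
    z = rng.normal(0.0, z_spread_um, n_emitters)
    brightness = rng.gamma(4.0, brightness_mean / 4.0, n_emitters) + 1e-3
    probe = np.array([probe_names[i] for i in rng.integers(0, n_probes, n_emitters)], dtype=object)
    fid = rng.random(n_emitters) < fiducial_fraction
    return VirtualSample(
        x_um=x,
        y_um=y,
        z_um=z,
        brightness=brightness,
        probe=probe,
        is_fiducial=fid,
        probe_names=probe_names,
        field_um=float(field_um),
        surface_z_um=float(surface_z_um),
        drift_rate_nm_s=float(drift_rate_nm_s),
        diffusion_nm2_s=float(diffusion_nm2_s),
        seed=int(seed),
    )


# ---------------------------------------------------------------------------
# State containers
# ---------------------------------------------------------------------------


@dataclass
class StageState:
    """Combined lateral + axial sample position at an instant."""

    x_um: float
    y_um: float
    piezo_z_um: float
    settled: bool


@dataclass
class LaserBank:
    """Excitation intensities (percent) per visible line plus the IR line."""

    intensity: dict = field(default_factory=lambda: {line: 0.0 for line in VISIBLE_LINES_NM})
    ir_785_on: bool = False

    def active_lines(self) -> list[int]:
        return [line for line, pct in self.intensity.items() if pct > 0]


@dataclass
class CameraSettings:
    exposure_ms: float = 50.0
    gain: float = 2.0  # counts per photon
    sensor_w: int = 512
    sensor_h: int = 512
    read_noise: float = 1.6  # counts RMS
    offset: float = 100.0  # counts
    pixel_um: float = 0.106

    def __post_init__(self) -> None:
        if self.exposure_ms <= 0:
            raise ValueError("exposure must be > 0")
        if self.sensor_w <= 0 or self.sensor_h <= 0:
            raise ValueError("sensor dimensions must be > 0")


@dataclass
class QPDReading:
    signal_v: float
    valid: bool
    timestamp_s: float


@dataclass
class FluidicsHardwareState:
    valve_position: int = 1
    needle_slot: tuple = (0, 0, 0)
    pressure_mbar: float = 0.0
    flow_ul_min: float = 0.0  # true plant flow
    volume_ul: float = 0.0  # integrated delivered volume


# ---------------------------------------------------------------------------
# Abstract device interfaces (the contract real drivers would implement)
# ---------------------------------------------------------------------------


class CameraInterface(ABC):
    @property
    @abstractmethod
    def settings(self) -> CameraSettings: ...

    @abstractmethod
    def snap(self, sample: VirtualSample, stage: StageState, lasers: LaserBank) -> np.ndarray: ...


class LightSourceInterface(ABC):
    @abstractmethod
    def set_intensity(self, line_nm: int, percent: float) -> None: ...

    @abstractmethod
    def set_ir(self, on: bool) -> None: ...

    @abstractmethod
    def all_off(self) -> None: ...


class FilterWheelInterface(ABC):
    @abstractmethod
    def set_position(self, position: int) -> None: ...


class XYStageInterface(ABC):
    @abstractmethod
    def move_to(self, x_um: float, y_um: float) -> None: ...

    @property
    @abstractmethod
    def settled(self) -> bool: ...


class ZPiezoInterface(ABC):
    @abstractmethod
    def move_to(self, z_um: float) -> None: ...

    @property
    @abstractmethod
    def position_um(self) -> float: ...

    @property
    @abstractmethod
    def settled(self) -> bool: ...


class AutofocusSensorInterface(ABC):
    @abstractmethod
    def read(self, sample: VirtualSample, piezo_z_um: float, lasers: LaserBank) -> QPDReading: ...


class ValveInterface(ABC):
    @abstractmethod
    def set_valve(self, port: int) -> None: ...


class PumpInterface(ABC):
    @abstractmethod
    def set_pressure(self, mbar: float) -> None: ...


class FlowSensorInterface(ABC):
    @abstractmethod
    def measured_flow(self) -> float: ...


class NeedlePositionerInterface(ABC):
    @abstractmethod
    def move_needle(self, slot: tuple) -> None: ...


class FluidicsPlantInterface(
    ValveInterface, PumpInterface, FlowSensorInterface, NeedlePositionerInterface
):
    """Combined contract for a fully plumbed fluidics rig."""


# ---------------------------------------------------------------------------
# Image formation
# ---------------------------------------------------------------------------


def expected_image(
    sample: VirtualSample,
    stage: StageState,
    lasers: LaserBank,
    cam: CameraSettings,
    sigma0_px: float = 1.3,
    z_r_um: float = 0.4,
) -> np.ndarray:
    """Noise-free expected photon map (photons per pixel, offset excluded).

    The camera field of view is centered on the stage position; emitter
    (x, y) maps to pixel ``(col, row) = ((x - stage.x)/pixel + (w-1)/2, ...)``
    with pixel (0, 0) at the top-left. Each emitter contributes an isotropic
    Gaussian of total weight ``brightness * exposure * intensity/100``, with
    width ``sigma0_px * sqrt(1 + (dz/z_R)^2)`` where
    ``dz = piezo_z - (surface_z + emitter_z)``.
    """
    h, w = cam.sensor_h, cam.sensor_w
    photons = np.zeros((h, w), dtype=float)
    for line in lasers.active_lines():
        pct = lasers.intensity[line]
        mask = sample.visible_mask(line)
        if not mask.any():
            continue
        xs = (sample.x_um[mask] - stage.x_um) / cam.pixel_um + (w - 1) / 2.0
        ys = (sample.y_um[mask] - stage.y_um) / cam.pixel_um + (h - 1) / 2.0
        dz = stage.piezo_z_um - (sample.surface_z_um + sample.z_um[mask])
        sigmas = sigma0_px * np.sqrt(1.0 + (dz / z_r_um) ** 2)
        totals = sample.brightness[mask] * cam.exposure_ms * pct / 100.0
        for cx, cy, sigma, total in zip(xs, ys, sigmas, totals):
            half = int(np.ceil(4 * sigma)) + 1
            c0, c1 = int(np.floor(cx)) - half, int(np.floor(cx)) + half + 1
            r0, r1 = int(np.floor(cy)) - half, int(np.floor(cy)) + half + 1
            c0, c1 = max(c0, 0), min(c1, w)
            r0, r1 = max(r0, 0), min(r1, h)
            if c0 >= c1 or r0 >= r1:
                continue
            cols = np.arange(c0, c1)
            rows = np.arange(r0, r1)
            gx = np.exp(-0.5 * ((cols - cx) / sigma) ** 2)
            gy = np.exp(-0.5 * ((rows - cy) / sigma) ** 2)
            patch = np.outer(gy, gx)
            s = patch.sum()
            if s > 0:
                photons[r0:r1, c0:c1] += total * patch / s
    return photons


def render_frame(
    sample: VirtualSample,
    stage: StageState,
    lasers: LaserBank,
    cam: CameraSettings,
    rng: np.random.Generator,
    sigma0_px: float = 1.3,
    z_r_um: float = 0.4,
) -> np.ndarray:
    """One camera exposure: offset + read noise + Poisson photon counts.

    Requires a settled stage; an exposure on a moving stage is refused the
    way a hardware-triggered camera would drop the frame.
    """
    if not stage.settled:
        raise HardwareError("camera triggered while the stage is not settled")
    if cam.exposure_ms <= 0:
        raise ValueError("exposure must be > 0")
    photons = expected_image(sample, stage, lasers, cam, sigma0_px, z_r_um)
    counts = (
        cam.offset
        + cam.gain * rng.poisson(photons)
        + rng.normal(0.0, cam.read_noise, photons.shape)
    )
    return np.clip(np.rint(counts), 0, 65535).astype(np.uint16)


def read_qpd(
    stage: StageState,
    sample: VirtualSample,
    lasers: LaserBank,
    gain_v_per_um: float = 0.5,
    offset_v: float = 0.0,
    noise_v: float = 0.005,
    rng: np.random.Generator | None = None,
    timestamp_s: float = 0.0,
) -> QPDReading:
    """Quadrant-photodiode reading: linear in defocus, gated on the IR laser."""
    if not lasers.ir_785_on:
        return QPDReading(signal_v=0.0, valid=False, timestamp_s=timestamp_s)
    signal = gain_v_per_um * (stage.piezo_z_um - sample.surface_z_um) + offset_v
    if noise_v > 0 and rng is not None:
        signal += rng.normal(0.0, noise_v)
    return QPDReading(signal_v=float(signal), valid=True, timestamp_s=timestamp_s)


def step_fluidics(
    state: FluidicsHardwareState,
    dt_s: float,
    k_flow: float = 1.25,
    tau_s: float = 2.0,
) -> FluidicsHardwareState:
    """Advance the first-order pump plant by ``dt`` (exact exponential update).

    ``d(flow)/dt = (k_flow * pressure - flow) / tau``; the delivered volume is
    the trapezoidal integral of the true flow (µl, with flow in µl/min).
    """
    if dt_s <= 0:
        raise ValueError("dt must be > 0")
    target = k_flow * state.pressure_mbar
    new_flow = target + (state.flow_ul_min - target) * np.exp(-dt_s / tau_s)
    state.volume_ul += 0.5 * (state.flow_ul_min + new_flow) * dt_s / 60.0
    state.flow_ul_min = float(new_flow)
    return state


# ---------------------------------------------------------------------------
# Simulated devices
# ---------------------------------------------------------------------------


class _Device:
    """Shared plumbing: role name, clock, RNG substream, optional event log."""

    allowed_options: frozenset = frozenset()

    def __init__(self, role: str, clock: SimClock, rng: np.random.Generator) -> None:
        self.role = role
        self.clock = clock
        self.rng = rng
        self.log = None  # set by the registry; a core_registry.RunLog

    def _log(self, message: str) -> None:
        if self.log is not None:
            self.log.append("INFO", self.role, message)

    def intrinsics(self) -> dict:
        """Device-intrinsic parameters, used by configuration swap reports."""
        return {}


class SimulatedCamera(_Device, CameraInterface):
    allowed_options = frozenset(
        {
            "exposure_ms",
            "gain",
            "sensor_w",
            "sensor_h",
            "read_noise",
            "offset",
            "pixel_um",
            "sigma0_px",
            "z_r_um",
        }
    )

    def __init__(self, role, clock, rng, **options) -> None:
        super().__init__(role, clock, rng)
        self.sigma0_px = float(options.pop("sigma0_px", 1.3))
        self.z_r_um = float(options.pop("z_r_um", 0.4))
        self._settings = CameraSettings(**options)

    @property
    def settings(self) -> CameraSettings:
        return self._settings

    def set_exposure(self, exposure_ms: float) -> None:
        if exposure_ms <= 0:
            raise ValueError("exposure must be > 0")
        self._settings.exposure_ms = float(exposure_ms)

    def snap(self, sample, stage, lasers) -> np.ndarray:
        frame = render_frame(
            sample, stage, lasers, self._settings, self.rng, self.sigma0_px, self.z_r_um
        )
        self._log(f"snap exposure={self._settings.exposure_ms}ms")
        return frame

    def intrinsics(self) -> dict:
        s = self._settings
        return {
            "sensor": (s.sensor_h, s.sensor_w),
            "gain": s.gain,
            "read_noise": s.read_noise,
            "offset": s.offset,
            "pixel_um": s.pixel_um,
        }


class SimulatedLaserBank(_Device, LightSourceInterface):
    allowed_options = frozenset()

    def __init__(self, role, clock, rng, **options) -> None:
        super().__init__(role, clock, rng)
        self.state = LaserBank()

    def set_intensity(self, line_nm: int, percent: float) -> None:
        if line_nm not in self.state.intensity:
            raise ValueError(f"unknown laser line {line_nm} nm (have {VISIBLE_LINES_NM})")
        if not 0.0 <= percent <= 100.0:
            raise ValueError("intensity must be within [0, 100] %")
        self.state.intensity[line_nm] = float(percent)
        self._log(f"laser {line_nm}nm -> {percent}%")

    def set_ir(self, on: bool) -> None:
        self.state.ir_785_on = bool(on)
        self._log(f"ir785 -> {'on' if on else 'off'}")

    def all_off(self) -> None:
        for line in self.state.intensity:
            self.state.intensity[line] = 0.0
        self.state.ir_785_on = False
        self._log("all lasers off")


class SimulatedFilterWheel(_Device, FilterWheelInterface):
    allowed_options = frozenset({"n_positions", "settle_s"})

    def __init__(self, role, clock, rng, n_positions: int = 6, settle_s: float = 0.1) -> None:
        super().__init__(role, clock, rng)
        self.n_positions = int(n_positions)
        self.settle_s = float(settle_s)
        self.position = 1

    def set_position(self, position: int) -> None:
        if not 1 <= position <= self.n_positions:
            raise HardwareError(f"filter position {position} outside 1..{self.n_positions}")
        self.position = int(position)
        self._log(f"filter -> {position}")

    def intrinsics(self) -> dict:
        return {"n_positions": self.n_positions}


class _SettlingAxis:
    """Settle-time bookkeeping shared by the XY stage and the piezo."""

    def __init__(self, clock: SimClock, settle_s: float) -> None:
        self._clock = clock
        self._settle_s = settle_s
        self._settle_until = 0.0

    def _start_move(self) -> None:
        self._settle_until = self._clock.now + self._settle_s

    @property
    def settled(self) -> bool:
        return self._clock.now >= self._settle_until

    def wait_settled(self) -> None:
        remaining = self._settle_until - self._clock.now
        if remaining > 0:
            self._clock.advance(remaining)


class SimulatedXYStage(_Device, XYStageInterface):
    allowed_options = frozenset({"settle_s", "travel_um"})

    def __init__(self, role, clock, rng, settle_s: float = 0.05, travel_um: float = XY_TRAVEL_UM):
        super().__init__(role, clock, rng)
        self.travel_um = float(travel_um)
        self.x_um = 0.0
        self.y_um = 0.0
        self._axis = _SettlingAxis(clock, float(settle_s))

    def move_to(self, x_um: float, y_um: float) -> None:
        t = self.travel_um
        if not (-t <= x_um <= t and -t <= y_um <= t):
            raise TravelError(
                f"XY target ({x_um}, {y_um}) µm outside travel ±{t} µm"
            )
        if (x_um, y_um) != (self.x_um, self.y_um):
            self._axis._start_move()
            self.x_um, self.y_um = float(x_um), float(y_um)
            self._log(f"move xy -> ({x_um:.2f}, {y_um:.2f}) µm")

    @property
    def settled(self) -> bool:
        return self._axis.settled

    def wait_settled(self) -> None:
        self._axis.wait_settled()

    def intrinsics(self) -> dict:
        return {"travel_um": self.travel_um}


class SimulatedPiezo(_Device, ZPiezoInterface):
    allowed_options = frozenset({"settle_s", "travel_um"})

    def __init__(self, role, clock, rng, settle_s: float = 0.02, travel_um=PIEZO_TRAVEL_UM):
        super().__init__(role, clock, rng)
        self.travel_um = (float(travel_um[0]), float(travel_um[1]))
        self._z_um = 50.0
        self._axis = _SettlingAxis(clock, float(settle_s))

    def move_to(self, z_um: float) -> None:
        lo, hi = self.travel_um
        if not lo <= z_um <= hi:
            raise TravelError(f"piezo target {z_um} µm outside travel {lo}–{hi} µm")
        if z_um != self._z_um:
            self._axis._start_move()
            self._z_um = float(z_um)

    @property
    def position_um(self) -> float:
        return self._z_um

    @property
    def settled(self) -> bool:
        return self._axis.settled

    def wait_settled(self) -> None:
        self._axis.wait_settled()

    def intrinsics(self) -> dict:
        return {"travel_um": self.travel_um}


class SimulatedQPD(_Device, AutofocusSensorInterface):
    allowed_options = frozenset({"gain_v_per_um", "offset_v", "noise_v"})

    def __init__(self, role, clock, rng, gain_v_per_um=0.5, offset_v=0.0, noise_v=0.005):
        super().__init__(role, clock, rng)
        self.gain_v_per_um = float(gain_v_per_um)
        self.offset_v = float(offset_v)
        self.noise_v = float(noise_v)

    def read(self, sample, piezo_z_um, lasers) -> QPDReading:
        stage = StageState(0.0, 0.0, piezo_z_um, settled=True)
        return read_qpd(
            stage,
            sample,
            lasers,
            gain_v_per_um=self.gain_v_per_um,
            offset_v=self.offset_v,
            noise_v=self.noise_v,
            rng=self.rng,
            timestamp_s=self.clock.now,
        )

    def intrinsics(self) -> dict:
        return {"gain_v_per_um": self.gain_v_per_um, "noise_v": self.noise_v}


class SimulatedFluidics(_Device, FluidicsPlantInterface):
    """Combined valve + pump + flow sensor + needle positioner plant.

    A single object keeps the plant state consistent: the pump pressure drives
    the flow, the flow sensor observes the same flow with Gaussian noise, and
    the delivered volume is its trapezoidal integral. The plant is stepped on
    every clock advance (in sub-steps, so large incubation advances keep the
    quadrature accurate).
    """

    allowed_options = frozenset(
        {"n_ports", "k_flow", "tau_s", "sensor_noise_ul_min", "max_pressure_mbar", "valve_move_s"}
    )
    MAX_SUBSTEP_S = 0.25

    def __init__(
        self,
        role,
        clock,
        rng,
        n_ports: int = 8,
        k_flow: float = 1.25,
        tau_s: float = 2.0,
        sensor_noise_ul_min: float = 2.0,
        max_pressure_mbar: float = 1000.0,
        valve_move_s: float = 0.5,
    ) -> None:
        super().__init__(role, clock, rng)
        self.n_ports = int(n_ports)
        self.k_flow = float(k_flow)
        self.tau_s = float(tau_s)
        self.sensor_noise_ul_min = float(sensor_noise_ul_min)
        self.max_pressure_mbar = float(max_pressure_mbar)
        self.valve_move_s = float(valve_move_s)
        self.state = FluidicsHardwareState()
        clock.subscribe(self._on_advance)

    # -- plant dynamics -----------------------------------------------------
    def _on_advance(self, dt_s: float) -> None:
        remaining = dt_s
        while remaining > 1e-12:
            step = min(remaining, self.MAX_SUBSTEP_S)
            step_fluidics(self.state, step, self.k_flow, self.tau_s)
            remaining -= step

    # -- interfaces ---------------------------------------------------------
    def set_valve(self, port: int) -> None:
        if not 1 <= port <= self.n_ports:
            raise HardwareError(f"valve port {port} outside 1..{self.n_ports}")
        self.state.valve_position = int(port)
        self._log(f"valve -> port {port}")

    def move_needle(self, slot) -> None:
        slot = tuple(int(v) for v in slot)
        if len(slot) != 3:
            raise ValueError("needle slot is a 3-axis index")
        self.state.needle_slot = slot
        self._log(f"needle -> {slot}")

    def set_pressure(self, mbar: float) -> None:
        self.state.pressure_mbar = float(np.clip(mbar, 0.0, self.max_pressure_mbar))
        if mbar != self.state.pressure_mbar:
            self._log(f"pressure clamped to {self.state.pressure_mbar} mbar")

    def measured_flow(self) -> float:
        noise = self.rng.normal(0.0, self.sensor_noise_ul_min) if self.sensor_noise_ul_min else 0.0
        return max(0.0, self.state.flow_ul_min + noise)

    def reset_volume(self) -> None:
        self.state.volume_ul = 0.0

    @property
    def true_flow(self) -> float:
        return self.state.flow_ul_min

    @property
    def volume_ul(self) -> float:
        return self.state.volume_ul

    def intrinsics(self) -> dict:
        return {
            "n_ports": self.n_ports,
            "k_flow": self.k_flow,
            "tau_s": self.tau_s,
            "max_pressure_mbar": self.max_pressure_mbar,
        }
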