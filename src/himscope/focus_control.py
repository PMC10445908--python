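"""Autofocus calibration, PID focus lock and per-ROI focus search.

The autofocus sensor is a quadrant photodiode (QPD) reading the reflection
of a 785 nm infrared laser; its voltage is linear in the objective–sample
distance near focus. Calibration performs a short axial ramp (2 µm by
default) of the piezo while recording the QPD, fits a line, and accepts the
calibration only if the response is monotonic and its *precision* — the RMS
residual of the linear fit converted to nanometres through the fitted slope
— is below 30 nm. A valid calibration supplies the volt↔nanometre
conversion used by the PID focus lock and by the per-ROI focus search that
defines each 3D stack's reference position (1–2 µm below the focal plane).

The precision metric is a design choice: the validity bound is stated as a
length, and the fit residual expressed through the slope is the most direct
length-equivalent of the ramp's voltage scatter.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from .hardware_model import (
    AutofocusSensorInterface,
    HardwareError,
    LightSourceInterface,
    SimClock,
    ZPiezoInterface,
)

__all__ = [
    "CalibrationResult",
    "PIDParams",
    "PIDController",
    "FocusSetpoint",
    "CalibrationError",
    "calibrate_autofocus",
    "run_focus_lock",
    "find_focus_and_reference",
    "FocusLogic",
    "PRECISION_BOUND_NM",
    "DEFAULT_RAMP_UM",
    "DEFAULT_RAMP_STEPS",
]

PRECISION_BOUND_NM = 30.0
DEFAULT_RAMP_UM = 2.0
DEFAULT_RAMP_STEPS = 21


class CalibrationError(RuntimeError):
    """Calibration could not run (IR laser off, too few steps, travel)."""


@dataclass
class CalibrationResult:
    """Linear fit of QPD signal vs piezo z over the calibration ramp.

    ``valid`` is exactly ``monotonic and precision_nm < 30``.
    """

    slope_v_per_um: float
    offset_v: float
    precision_nm: float
    monotonic: bool
    valid: bool
    ramp: list  # list of (z_um, signal_v)

    def to_yaml(self, path) -> None:
        doc = {
            "slope_v_per_um": float(self.slope_v_per_um),
            "offset_v": float(self.offset_v),
            "precision_nm": float(self.precision_nm),
            "monotonic": bool(self.monotonic),
            "valid": bool(self.valid),
            "ramp": [[float(z), float(s)] for z, s in self.ramp],
        }
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False), encoding="utf-8")


@dataclass
class PIDParams:
    """Discrete positional-form PID tuning.

    ``kp`` is dimensionless gain on the error, ``ki`` per second, ``kd``
    seconds; output and integral limits are in output units.
    """

    kp: float = 0.6
    ki: float = 0.2
    kd: float = 0.0
    output_limits: tuple = (-5.0, 5.0)
    integral_limit: float = 5.0
    period_s: float = 0.1

    def __post_init__(self) -> None:
        if self.period_s <= 0:
            raise ValueError("loop period must be > 0")
        lo, hi = self.output_limits
        if lo >= hi:
            raise ValueError("output limits must be ordered (lo < hi)")


class PIDController:
    """Positional discrete PID with clamped-integral anti-windup.

    Per step: ``u = kp*e + I' + kd*(e - e_prev)/dt`` with tentative integral
    ``I' = clip(I + ki*e*dt, ±integral_limit)``. If ``u`` exceeds the output
    limits the output is clamped **and the integral is frozen** at its
    previous value (windup protection); otherwise ``I'`` is committed.
    """

    def __init__(self, params: PIDParams) -> None:
        self.params = params
        self.integral = 0.0
        self.prev_error: float | None = None

    def reset(self) -> None:
        self.integral = 0.0
        self.prev_error = None

    def step(self, error: float, dt_s: float | None = None) -> float:
        p = self.params
        dt = p.period_s if dt_s is None else dt_s
        if dt <= 0:
            raise ValueError("dt must be > 0")
        tentative = float(np.clip(self.integral + p.ki * error * dt, -p.integral_limit, p.integral_limit))
        derivative = 0.0 if self.prev_error is None else (error - self.prev_error) / dt
        u = p.kp * error + tentative + p.kd * derivative
        lo, hi = p.output_limits
        if u > hi:
            u = hi  # saturated: freeze integral
        elif u < lo:
            u = lo
        else:
            self.integral = tentative
        self.prev_error = error
        return u


def pid_step(params: PIDParams, state: PIDController | None, error: float, dt_s: float):
    """Functional wrapper: one PID update returning (correction, state)."""
    controller = state if state is not None else PIDController(params)
    return controller.step(error, dt_s), controller


@dataclass
class FocusSetpoint:
    """Focal position of one ROI and the axial start of its 3D stack."""

    qpd_setpoint_v: float
    focal_z_um: float
    reference_z_um: float
    below_offset_um: float = 1.5


# ---------------------------------------------------------------------------
# Operations (device-level; FocusLogic binds them to wired modules)
# ---------------------------------------------------------------------------


def calibrate_autofocus(
    qpd: AutofocusSensorInterface,
    piezo: ZPiezoInterface,
    lasers,
    sample,
    clock: SimClock,
    ramp_um: float = DEFAULT_RAMP_UM,
    n_steps: int = DEFAULT_RAMP_STEPS,
) -> CalibrationResult:
    """Axial calibration ramp of the QPD response.

    Steps the piezo over ``ramp_um`` (centered on the current position,
    moving upward), records the QPD at each settled position, and fits
    signal = slope*z + offset by least squares. Precision is the RMS fit
    residual divided by |slope|, in nm.
    """
    if n_steps < 3:
        raise CalibrationError("calibration needs at least 3 ramp steps")
    if not lasers.state.ir_785_on:
        raise CalibrationError("785 nm laser is off; cannot read the autofocus sensor")
    z0 = piezo.position_um
    zs = z0 + np.linspace(-ramp_um / 2.0, ramp_um / 2.0, n_steps)
    lo, hi = piezo.travel_um
    if zs[0] < lo or zs[-1] > hi:
        raise CalibrationError(
            f"ramp {zs[0]:.2f}–{zs[-1]:.2f} µm outside piezo travel {lo}–{hi} µm"
        )
    signals = np.empty(n_steps)
    for i, z in enumerate(zs):
        piezo.move_to(float(z))
        piezo.wait_settled()
        signals[i] = qpd.read(sample, piezo.position_um, lasers.state).signal_v
    piezo.move_to(float(z0))
    piezo.wait_settled()
    return fit_calibration(zs, signals)


def fit_calibration(zs: np.ndarray, signals: np.ndarray) -> CalibrationResult:
    """Least-squares line fit + the monotonicity/precision validity rule."""
    zs = np.asarray(zs, dtype=float)
    signals = np.asarray(signals, dtype=float)
    slope, offset = np.polyfit(zs, signals, 1)
    residuals = signals - (slope * zs + offset)
    rms_v = float(np.sqrt(np.mean(residuals**2)))
    precision_nm = float("inf") if slope == 0 else rms_v / abs(slope) * 1e3
    diffs = np.diff(signals)
    monotonic = bool(np.all(diffs > 0) or np.all(diffs < 0))
    valid = monotonic and precision_nm < PRECISION_BOUND_NM
    return CalibrationResult(
        slope_v_per_um=float(slope),
        offset_v=float(offset),
        precision_nm=precision_nm,
        monotonic=monotonic,
        valid=valid,
        ramp=list(zip(zs.tolist(), signals.tolist())),
    )


def run_focus_lock(
    setpoint_v: float,
    calibration: CalibrationResult,
    params: PIDParams,
    duration_s: float,
    qpd,
    piezo,
    lasers,
    sample,
    clock: SimClock,
) -> list:
    """Closed-loop focus stabilization at the PID loop period.

    Each iteration reads the QPD, converts the voltage error to µm through
    the calibration slope, and commands a piezo correction clamped to
    travel. Returns the lock trace as (t_s, error_nm) pairs.
    """
    if not calibration.valid:
        raise CalibrationError("refusing to lock focus on an invalid calibration")
    controller = PIDController(params)
    trace = []
    n_iter = max(1, int(round(duration_s / params.period_s)))
    lo, hi = piezo.travel_um
    for _ in range(n_iter):
        reading = qpd.read(sample, piezo.position_um, lasers.state)
        if not reading.valid:
            raise CalibrationError("autofocus sensor reading invalid (IR laser off?)")
        error_um = (setpoint_v - reading.signal_v) / calibration.slope_v_per_um
        trace.append((clock.now, error_um * 1e3))
        correction = controller.step(error_um)
        target = float(np.clip(piezo.position_um + correction, lo, hi))
        piezo.move_to(target)
        piezo.wait_settled()
        clock.advance(max(0.0, params.period_s - (clock.now - trace[-1][0])))
    return trace


def find_focus_and_reference(
    setpoint_v: float,
    calibration: CalibrationResult,
    qpd,
    piezo,
    lasers,
    sample,
    clock: SimClock,
    below_offset_um: float = 1.5,
    n_average: int = 8,
    max_iter: int = 6,
) -> FocusSetpoint:
    """Return the piezo to the stored QPD setpoint and define the stack start.

    Iterates piezo corrections from averaged QPD readings until the residual
    is below the sensor noise floor, then sets
    ``reference_z = focal_z - below_offset`` (axial start of the stack, 1–2 µm
    below the focal plane so the stack brackets the sample).
    """
    if not calibration.valid:
        raise CalibrationError("refusing focus search on an invalid calibration")
    if below_offset_um <= 0:
        raise ValueError("below-offset must be positive")
    lo, hi = piezo.travel_um
    for _ in range(max_iter):
        readings = []
        for _ in range(n_average):
            r = qpd.read(sample, piezo.position_um, lasers.state)
            if not r.valid:
                raise CalibrationError("autofocus sensor reading invalid (IR laser off?)")
            readings.append(r.signal_v)
        error_um = (setpoint_v - float(np.mean(readings))) / calibration.slope_v_per_um
        if abs(error_um) < 2e-3:  # 2 nm: below the per-ROI repeatability target
            break
        target = piezo.position_um + error_um
        if not lo <= target <= hi:
            raise HardwareError(f"focal search target {target:.2f} µm outside piezo travel")
        piezo.move_to(target)
        piezo.wait_settled()
    focal_z = piezo.position_um
    reference_z = focal_z - below_offset_um
    if not lo <= reference_z <= hi:
        raise HardwareError(
            f"stack reference {reference_z:.2f} µm outside piezo travel {lo}–{hi} µm"
        )
    return FocusSetpoint(
        qpd_setpoint_v=float(setpoint_v),
        focal_z_um=float(focal_z),
        reference_z_um=float(reference_z),
        below_offset_um=float(below_offset_um),
    )


# ---------------------------------------------------------------------------
# Wired logic module
# ---------------------------------------------------------------------------


class FocusLogic:
    """Focus toolbox bound to a wired QPD + piezo + laser bank."""

    required_connectors = {
        "qpd": AutofocusSensorInterface,
        "piezo": ZPiezoInterface,
        "lasers": LightSourceInterface,
    }

    def __init__(self, role, graph, qpd, piezo, lasers) -> None:
        self.role = role
        self.graph = graph
        self.qpd = qpd
        self.piezo = piezo
        self.lasers = lasers
        self.calibration: CalibrationResult | None = None
        self.setpoint_v: float | None = None

    def calibrate(self, ramp_um: float = DEFAULT_RAMP_UM, n_steps: int = DEFAULT_RAMP_STEPS):
        self.lasers.set_ir(True)
        result = calibrate_autofocus(
            self.qpd, self.piezo, self.lasers, self.graph.sample, self.graph.clock,
            ramp_um=ramp_um, n_steps=n_steps,
        )
        self.calibration = result
        if result.valid:
            # store the current (in-focus) QPD voltage as the lock setpoint
            reading = self.qpd.read(self.graph.sample, self.piezo.position_um, self.lasers.state)
            self.setpoint_v = reading.signal_v
        return result

    def lock(self, duration_s: float, params: PIDParams | None = None):
        if self.setpoint_v is None:
            raise CalibrationError("no focus setpoint stored; calibrate first")
        return run_focus_lock(
            self.setpoint_v, self.calibration, params or PIDParams(), duration_s,
            self.qpd, self.piezo, self.lasers, self.graph.sample, self.graph.clock,
        )

    def find_reference(self, below_offset_um: float = 1.5) -> FocusSetpoint:
        if self.setpoint_v is None:
            raise CalibrationError("no focus setpoint stored; calibrate first")
        return find_focus_and_reference(
            self.setpoint_v, self.calibration,
            self.qpd, self.piezo, self.lasers, self.graph.sample, self.graph.clock,
            below_offset_um=below_offset_um,
        )

    def exercise(self) -> dict:
        """Minimal scripted use for hardware-swap equivalence checks."""
        self.lasers.set_ir(True)
        reading = self.qpd.read(self.graph.sample, self.piezo.position_um, self.lasers.state)
        self.lasers.set_ir(False)
        return {"read_valid": reading.valid}
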