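"""Injection sequences and PID flow control against the fluidics plant.

A sequential hybridization experiment alternates chemistry and imaging: each
chemistry block is an *injection sequence* — an ordered list of steps, each
naming a product, a valve port (and, for cycle-specific probes, a tray slot
for the pipetting-robot needle), a target volume, a target flow rate and an
optional incubation. During a step the measured flow rate is regulated to
its target by a PID loop acting on the pump pressure; the step advances when
the integrated delivered volume reaches the target, after which the pump is
switched off and the incubation elapses on the virtual clock with no flow.

Typical steps inject 1–2 ml at 150–300 µl/min. A step whose flow never
reaches 10 % of target within the fault timeout is reported as a fault
(blocked line) with the pump commanded off — necessary engineering for
multi-day unattended runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .focus_control import PIDController, PIDParams
from .hardware_model import FluidicsPlantInterface

__all__ = [
    "InjectionStep",
    "InjectionSequence",
    "TrayLayout",
    "FluidicsLimits",
    "StepReport",
    "SequenceReport",
    "SequenceError",
    "StopToken",
    "validate_sequence",
    "save_sequence",
    "load_sequence",
    "FluidicsLogic",
    "FLOW_LOOP_PERIOD_S",
    "FAULT_TIMEOUT_S",
]

FLOW_LOOP_PERIOD_S = 0.1
FAULT_TIMEOUT_S = 30.0
DEFAULT_FLOW_PID = PIDParams(
    kp=0.8, ki=0.5, kd=0.0, output_limits=(0.0, 1000.0), integral_limit=1000.0,
    period_s=FLOW_LOOP_PERIOD_S,
)


class SequenceError(ValueError):
    """An injection sequence file or runtime precondition is invalid."""


@dataclass
class InjectionStep:
    product: str
    valve: int
    volume_ul: float
    flow_ul_min: float
    incubation_s: float = 0.0
    tray_slot: tuple | None = None  # 3-axis index for cycle-specific probes


@dataclass
class InjectionSequence:
    name: str
    steps: list


@dataclass
class TrayLayout:
    """Probe name -> 3-axis position on the pipetting-robot delivery tray."""

    slots: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        positions = [tuple(v) for v in self.slots.values()]
        if len(set(positions)) != len(positions):
            raise SequenceError("tray layout assigns the same slot to two probes")

    def slot_of(self, probe: str) -> tuple:
        if probe not in self.slots:
            raise SequenceError(f"probe {probe!r} not present on the delivery tray")
        return tuple(self.slots[probe])


@dataclass
class FluidicsLimits:
    n_ports: int = 8
    max_flow_ul_min: float = 1000.0
    max_pressure_mbar: float = 1000.0


@dataclass
class StepReport:
    product: str
    delivered_ul: float
    mean_flow_ul_min: float
    duration_s: float
    fault: bool = False
    fault_reason: str = ""
    flow_trace: list = field(default_factory=list)  # (t_s, measured µl/min)


@dataclass
class SequenceReport:
    name: str
    steps: list  # StepReport
    aborted: bool = False
    completed: bool = False

    @property
    def total_delivered_ul(self) -> float:
        return sum(s.delivered_ul for s in self.steps)


class StopToken:
    """Cooperative cancellation checked at every control tick."""

    def __init__(self) -> None:
        self.requested = False

    def request(self) -> None:
        self.requested = True


# ---------------------------------------------------------------------------
# Validation and persistence
# ---------------------------------------------------------------------------


def validate_sequence(seq: InjectionSequence, limits: FluidicsLimits | None = None) -> list[str]:
    """Return a list of error strings (empty = valid); never raises.

    Errors cite the 1-based step index and the offending field. An empty
    sequence is valid but yields a warning-style record.
    """
    limits = limits or FluidicsLimits()
    errors: list[str] = []
    if not seq.name:
        errors.append("sequence name: must be nonempty")
    if not seq.steps:
        return ["warning: sequence has no steps"] if not errors else errors
    for i, step in enumerate(seq.steps, start=1):
        if not step.product:
            errors.append(f"step {i}, field product: must be nonempty")
        if not 1 <= step.valve <= limits.n_ports:
            errors.append(f"step {i}, field valve: port {step.valve} outside 1..{limits.n_ports}")
        if step.volume_ul < 0:
            errors.append(f"step {i}, field volume: must be >= 0 (got {step.volume_ul})")
        if step.volume_ul > 0 and step.flow_ul_min <= 0:
            errors.append(f"step {i}, field flow: must be > 0 when volume > 0")
        if step.flow_ul_min > limits.max_flow_ul_min:
            errors.append(
                f"step {i}, field flow: {step.flow_ul_min} µl/min exceeds pump "
                f"capability {limits.max_flow_ul_min}"
            )
        if step.incubation_s < 0:
            errors.append(f"step {i}, field incubation: must be >= 0")
        if step.tray_slot is not None and len(tuple(step.tray_slot)) != 3:
            errors.append(f"step {i}, field tray_slot: must be a 3-axis index")
    return errors


_STEP_KEYS = {"product", "valve", "tray_slot", "volume_ul", "flow_ul_min", "incubation_s"}


def save_sequence(seq: InjectionSequence, path) -> None:
    steps = []
    for step in seq.steps:
        entry = {
            "product": step.product,
            "valve": int(step.valve),
            "volume_ul": float(step.volume_ul),
            "flow_ul_min": float(step.flow_ul_min),
            "incubation_s": float(step.incubation_s),
        }
        if step.tray_slot is not None:
            entry["tray_slot"] = list(step.tray_slot)
        steps.append(entry)
    doc = {"name": seq.name, "steps": steps}
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False), encoding="utf-8")


def load_sequence(path) -> InjectionSequence:
    path = Path(path)
    if not path.exists():
        raise SequenceError(f"sequence file not found: {path}")
    doc = yaml.safe_load(path.read_text(encoding="utf-8"))
    if not isinstance(doc, dict) or "name" not in doc or "steps" not in doc:
        raise SequenceError("sequence file must be a mapping with 'name' and 'steps'")
    steps = []
    for i, entry in enumerate(doc["steps"] or [], start=1):
        if not isinstance(entry, dict):
            raise SequenceError(f"step {i}: not a mapping")
        extra = set(entry) - _STEP_KEYS
        if extra:
            raise SequenceError(f"step {i}: unknown fields {sorted(extra)}")
        missing = {"product", "valve", "volume_ul", "flow_ul_min"} - set(entry)
        if missing:
            raise SequenceError(f"step {i}: missing required field(s) {sorted(missing)}")
        steps.append(
            InjectionStep(
                product=str(entry["product"]),
                valve=int(entry["valve"]),
                volume_ul=float(entry["volume_ul"]),
                flow_ul_min=float(entry["flow_ul_min"]),
                incubation_s=float(entry.get("incubation_s", 0.0)),
                tray_slot=tuple(entry["tray_slot"]) if entry.get("tray_slot") else None,
            )
        )
    return InjectionSequence(name=str(doc["name"]), steps=steps)


# ---------------------------------------------------------------------------
# Execution
# ---------------------------------------------------------------------------


class FluidicsLogic:
    """Injection executor bound to the wired fluidics plant."""

    required_connectors = {"plant": FluidicsPlantInterface}

    def __init__(self, role, graph, plant) -> None:
        self.role = role
        self.graph = graph
        self.plant = plant
        self.pid_params = DEFAULT_FLOW_PID

    # -- single step --------------------------------------------------------
    def run_injection_step(
        self,
        step: InjectionStep,
        pid: PIDParams | None = None,
        stop: StopToken | None = None,
        on_tick=None,
    ) -> StepReport:
        """Deliver one step under PID flow control, then incubate.

        The controlled quantity is the integrated volume at the moment the
        volume trigger fires; the loop stops within one control tick of
        reaching the target. ``on_tick(t, measured_flow, delivered)`` is an
        optional progress hook (used by the status tracker).
        """
        plant = self.plant
        clock = self.graph.clock
        params = pid or self.pid_params
        controller = PIDController(params)
        dt = params.period_s
        t_start = clock.now
        trace: list = []
        delivered = 0.0
        fault = False
        fault_reason = ""
        if step.volume_ul > 0:
            plant.reset_volume()
            while True:
                if stop is not None and stop.requested:
                    break
                measured = plant.measured_flow()
                trace.append((clock.now - t_start, measured))
                pressure = controller.step(step.flow_ul_min - measured, dt)
                plant.set_pressure(pressure)
                clock.advance(dt)
                delivered = plant.volume_ul
                if on_tick is not None:
                    on_tick(clock.now, measured, delivered)
                if delivered >= step.volume_ul:
                    break
                elapsed = clock.now - t_start
                if elapsed > FAULT_TIMEOUT_S and plant.true_flow < 0.1 * step.flow_ul_min:
                    fault = True
                    fault_reason = (
                        f"flow {plant.true_flow:.1f} µl/min below 10% of target "
                        f"{step.flow_ul_min} µl/min after {FAULT_TIMEOUT_S:.0f} s (blocked line?)"
                    )
                    break
            plant.set_pressure(0.0)
            # drain: let the plant flow decay before the incubation window
            if not fault and not (stop is not None and stop.requested):
                drain_deadline = clock.now + 10.0 * plant.tau_s
                while plant.true_flow > 0.5 and clock.now < drain_deadline:
                    clock.advance(dt)
        aborted = stop is not None and stop.requested
        if step.incubation_s > 0 and not fault and not aborted:
            remaining = step.incubation_s
            while remaining > 0:
                chunk = min(1.0, remaining)
                clock.advance(chunk)
                remaining -= chunk
                if stop is not None and stop.requested:
                    aborted = True
                    break
        # post-settle mean flow: after the first-order rise (~5 tau + margin)
        settle_s = 8.0 * plant.tau_s
        settled = [f for t, f in trace if t >= settle_s]
        mean_flow = float(sum(settled) / len(settled)) if settled else 0.0
        report = StepReport(
            product=step.product,
            delivered_ul=float(delivered),
            mean_flow_ul_min=mean_flow,
            duration_s=float(clock.now - t_start),
            fault=fault,
            fault_reason=fault_reason,
            flow_trace=trace,
        )
        if self.graph.log is not None:
            self.graph.log.append(
                "WARN" if fault else "INFO",
                self.role,
                f"step {step.product}: delivered {report.delivered_ul:.1f} µl "
                f"in {report.duration_s:.1f} s" + (f" FAULT: {fault_reason}" if fault else ""),
            )
        return report

    # -- full sequence ------------------------------------------------------
    def run_sequence(
        self,
        seq: InjectionSequence,
        tray: TrayLayout | None = None,
        stop: StopToken | None = None,
        on_tick=None,
    ) -> SequenceReport:
        """Execute steps in order: valve, needle, PID delivery, incubation."""
        errors = [e for e in validate_sequence(seq) if not e.startswith("warning")]
        if errors:
            raise SequenceError("sequence invalid: " + "; ".join(errors))
        report = SequenceReport(name=seq.name, steps=[])
        for step in seq.steps:
            if stop is not None and stop.requested:
                report.aborted = True
                break
            self.plant.set_valve(step.valve)
            self.graph.clock.advance(self.plant.valve_move_s)
            if step.tray_slot is not None or (tray is not None and step.product in getattr(tray, "slots", {})):
                slot = step.tray_slot
                if slot is None:
                    slot = tray.slot_of(step.product)
                self.plant.move_needle(slot)
                self.graph.clock.advance(1.0)
            step_report = self.run_injection_step(step, stop=stop, on_tick=on_tick)
            report.steps.append(step_report)
            if step_report.fault:
                break
        if stop is not None and stop.requested:
            report.aborted = True
            self.plant.set_pressure(0.0)
        report.completed = (
            not report.aborted
            and len(report.steps) == len(seq.steps)
            and not any(s.fault for s in report.steps)
        )
        return report

    def exercise(self) -> dict:
        self.plant.set_pressure(50.0)
        self.graph.clock.advance(1.0)
        flow = self.plant.true_flow
        self.plant.set_pressure(0.0)
        return {"responded": flow > 0.0}
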