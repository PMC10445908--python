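"""Task state machine, experiment configuration and the full Hi-M task.

A multiplexed (Hi-M) experiment is a succession of hybridization / imaging /
chemical-bleaching cycles over a fixed set of ROIs. The runner implements:

* cycle 0 — injection of the nuclear stain + fiducial probes, then one
  reference stack per ROI;
* cycles 1..n — hybridize the cycle's probe, acquire a multicolor stack at
  every ROI (stage move, focus search, synchronized z-stack, file + metadata
  write, status update), then bleach.

Task control follows a table-driven state machine (stopped, starting,
running, pausing, paused, resuming, finishing). A *smooth* stop finishes the
current cycle before stopping; an *emergency* stop halts immediately,
switches every laser off and the pump to zero pressure. While a task owns
the rig, concurrent hardware commands from other entry points are rejected.

Experiment status is exported as a single YAML snapshot file via atomic
replace, so an external tracker can poll it at any instant and always parse
a complete document.
"""

from __future__ import annotations

import os
import tempfile
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np
import yaml

from .acquisition import (
    AcquisitionLogic,
    ImagingSettings,
    StackMetadata,
    format_filename,
    plan_stack,
    write_stack,
)
from .core_registry import ModuleGraph
from .fluidics_control import (
    FluidicsLogic,
    StopToken,
    TrayLayout,
    load_sequence,
    validate_sequence,
)
from .focus_control import FocusLogic
from .roi_planner import load_roi_list

__all__ = [
    "TaskState",
    "TaskEvent",
    "TransitionError",
    "transition",
    "TRANSITIONS",
    "ExperimentConfig",
    "validate_config",
    "StatusSnapshot",
    "write_status",
    "read_status",
    "preanalyze_stack",
    "PreAnalysis",
    "TaskRunner",
    "RunReport",
    "TaskFault",
]


class TaskState(str, Enum):
    STOPPED = "stopped"
    STARTING = "starting"
    RUNNING = "running"
    PAUSING = "pausing"
    PAUSED = "paused"
    RESUMING = "resuming"
    FINISHING = "finishing"


class TaskEvent(str, Enum):
    START = "start"
    STARTED = "started"
    PAUSE = "pause"
    PAUSED = "paused"
    RESUME = "resume"
    RESUMED = "resumed"
    FINISH = "finish"
    FINISHED = "finished"
    STOP_SMOOTH = "stop_smooth"
    STOP_EMERGENCY = "stop_emergency"


class TransitionError(RuntimeError):
    """Event not defined for the current state; the state is unchanged."""


# ``finishing`` means: complete the current cycle, then stop.
TRANSITIONS: dict = {
    (TaskState.STOPPED, TaskEvent.START): TaskState.STARTING,
    (TaskState.STARTING, TaskEvent.STARTED): TaskState.RUNNING,
    (TaskState.RUNNING, TaskEvent.PAUSE): TaskState.PAUSING,
    (TaskState.PAUSING, TaskEvent.PAUSED): TaskState.PAUSED,
    (TaskState.PAUSED, TaskEvent.RESUME): TaskState.RESUMING,
    (TaskState.RESUMING, TaskEvent.RESUMED): TaskState.RUNNING,
    (TaskState.RUNNING, TaskEvent.FINISH): TaskState.FINISHING,
    (TaskState.FINISHING, TaskEvent.FINISHED): TaskState.STOPPED,
    (TaskState.RUNNING, TaskEvent.STOP_SMOOTH): TaskState.FINISHING,
    (TaskState.PAUSING, TaskEvent.STOP_SMOOTH): TaskState.FINISHING,
    (TaskState.PAUSED, TaskEvent.STOP_SMOOTH): TaskState.FINISHING,
}
for _state in TaskState:
    if _state is not TaskState.STOPPED:
        TRANSITIONS[(_state, TaskEvent.STOP_EMERGENCY)] = TaskState.STOPPED


def transition(state: TaskState, event: TaskEvent) -> TaskState:
    """Table-driven transition; an undefined pair raises TransitionError."""
    state = TaskState(state)
    event = TaskEvent(event)
    try:
        return TRANSITIONS[(state, event)]
    except KeyError:
        raise TransitionError(
            f"event {event.value!r} not allowed in state {state.value!r}"
        ) from None


# ---------------------------------------------------------------------------
# Experiment configuration
# ---------------------------------------------------------------------------

TASK_TYPES = ("him_full", "stack_only", "fluidics_only", "cycle0_only")


@dataclass
class ExperimentConfig:
    task: str = "him_full"
    sample_name: str = "sample"
    save_root: str = "."
    imaging: ImagingSettings = field(default_factory=ImagingSettings)
    roi_file: str | None = None
    sequences: dict = field(default_factory=dict)  # cycle0 / hybridization / bleaching -> path
    probes: list = field(default_factory=list)  # [{cycle, name, tray_slot}]
    n_cycles: int = 0
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        path = Path(path)
        doc = yaml.safe_load(path.read_text(encoding="utf-8")) or {}
        imaging_doc = dict(doc.get("imaging") or {})
        channels = [tuple(c) for c in imaging_doc.pop("channels", [(561, 20.0), (640, 30.0)])]
        imaging = ImagingSettings(
            exposure_ms=float(imaging_doc.pop("exposure_ms", 50.0)),
            channels=channels,
            n_planes=int(imaging_doc.pop("n_planes", 60)),
            dz_nm=float(imaging_doc.pop("dz_nm", 250.0)),
            z_start_um=float(imaging_doc.pop("z_start_um", 48.5)),
            save_format=str(imaging_doc.pop("save_format", "tiff")),
        )
        if imaging_doc:
            raise ValueError(f"imaging: unknown fields {sorted(imaging_doc)}")
        return cls(
            task=str(doc.get("task", "him_full")),
            sample_name=str(doc.get("sample_name", "sample")),
            save_root=str(doc.get("save_root", ".")),
            imaging=imaging,
            roi_file=doc.get("roi_file"),
            sequences=dict(doc.get("sequences") or {}),
            probes=[dict(p) for p in (doc.get("probes") or [])],
            n_cycles=int(doc.get("n_cycles", 0)),
            seed=int(doc.get("seed", 0)),
        )

    def to_yaml(self, path) -> None:
        doc = {
            "task": self.task,
            "sample_name": self.sample_name,
            "save_root": str(self.save_root),
            "imaging": {
                "exposure_ms": self.imaging.exposure_ms,
                "channels": [list(c) for c in self.imaging.channels],
                "n_planes": self.imaging.n_planes,
                "dz_nm": self.imaging.dz_nm,
                "z_start_um": self.imaging.z_start_um,
                "save_format": self.imaging.save_format,
            },
            "roi_file": self.roi_file,
            "sequences": dict(self.sequences),
            "probes": [dict(p) for p in self.probes],
            "n_cycles": self.n_cycles,
            "seed": self.seed,
        }
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False), encoding="utf-8")


def validate_config(config: ExperimentConfig) -> list[str]:
    """Field-by-field validity check; returns error strings naming fields."""
    errors: list[str] = []
    if config.task not in TASK_TYPES:
        errors.append(f"task: unknown task type {config.task!r} (must be one of {TASK_TYPES})")
    if not config.sample_name:
        errors.append("sample_name: must be nonempty")
    if config.n_cycles < 0:
        errors.append("n_cycles: must be >= 0")
    try:
        ImagingSettings(
            exposure_ms=config.imaging.exposure_ms,
            channels=config.imaging.channels,
            n_planes=config.imaging.n_planes,
            dz_nm=config.imaging.dz_nm,
            z_start_um=config.imaging.z_start_um,
            save_format=config.imaging.save_format,
        )
    except ValueError as exc:
        msg = str(exc)
        fld = "dz" if "dz" in msg else ("exposure_ms" if "exposure" in msg else "imaging")
        errors.append(f"{fld}: {msg}")
    needs_imaging = config.task in ("him_full", "stack_only", "cycle0_only")
    if needs_imaging:
        if not config.roi_file:
            errors.append("roi_file: required for imaging tasks")
        elif not Path(config.roi_file).exists():
            errors.append(f"roi_file: file not found ({config.roi_file})")
    needs = {
        "him_full": ("cycle0", "hybridization", "bleaching"),
        "cycle0_only": ("cycle0",),
        "fluidics_only": ("cycle0",),
        "stack_only": (),
    }.get(config.task, ())
    for key in needs:
        path = config.sequences.get(key)
        if not path:
            errors.append(f"sequences.{key}: required for task {config.task!r}")
        elif not Path(path).exists():
            errors.append(f"sequences.{key}: file not found ({path})")
    if config.task == "him_full":
        if len(config.probes) != config.n_cycles:
            errors.append(
                f"probes: list length {len(config.probes)} must equal n_cycles "
                f"{config.n_cycles} for him_full"
            )
        for i, probe in enumerate(config.probes):
            if "name" not in probe:
                errors.append(f"probes[{i}].name: missing")
    if config.seed < 0:
        errors.append("seed: must be a non-negative integer")
    return errors


# ---------------------------------------------------------------------------
# Status tracker file interface
# ---------------------------------------------------------------------------


@dataclass
class StatusSnapshot:
    timestamp_s: float
    task_state: str
    cycle: int
    roi_id: str = ""
    fluidics_step: str = ""
    fluidics_flow_ul_min: float = 0.0
    fluidics_delivered_ul: float = 0.0
    preanalysis: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def write_status(snapshot: StatusSnapshot, path, log=None) -> None:
    """Serialize the snapshot atomically (write-temp + rename).

    A consumer polling ``path`` therefore always reads a complete YAML
    document. I/O errors are logged and swallowed: status reporting must
    never kill an experiment.
    """
    path = Path(path)
    try:
        fd, tmp = tempfile.mkstemp(prefix=path.name, dir=path.parent)
        with os.fdopen(fd, "w", encoding="utf-8") as fh:
            fh.write(yaml.safe_dump(snapshot.to_dict(), sort_keys=False))
        os.replace(tmp, path)
    except OSError as exc:
        if log is not None:
            log.append("WARN", "status", f"status write failed: {exc}")


def read_status(path) -> dict:
    return yaml.safe_load(Path(path).read_text(encoding="utf-8"))


# ---------------------------------------------------------------------------
# Real-time pre-analysis
# ---------------------------------------------------------------------------


@dataclass
class PreAnalysis:
    best_focus_plane: int
    sharpness: list  # per-plane intensity variance
    max_projection: np.ndarray


def preanalyze_stack(stack3d: np.ndarray) -> PreAnalysis:
    """Per-plane variance sharpness, best-focus plane and max projection.

    Ties in the sharpness trace resolve to the lowest plane index
    (``argmax`` semantics).
    """
    stack3d = np.asarray(stack3d)
    if stack3d.size == 0 or stack3d.ndim != 3:
        raise ValueError("pre-analysis needs a nonempty (planes, h, w) stack")
    sharpness = stack3d.astype(float).var(axis=(1, 2))
    return PreAnalysis(
        best_focus_plane=int(np.argmax(sharpness)),
        sharpness=[float(s) for s in sharpness],
        max_projection=stack3d.max(axis=0),
    )


# ---------------------------------------------------------------------------
# The Hi-M task runner
# ---------------------------------------------------------------------------


class TaskFault(RuntimeError):
    """A hardware fault or abort that moved the task to stopped."""


@dataclass
class RunReport:
    completed: bool
    state_history: list
    files: list
    cycles_done: int
    fault: str = ""
    schedule: list = field(default_factory=list)  # (cycle, roi_id, action)
    calibration_precision_nm: float = 0.0


class TaskRunner:
    """Drives a full experiment against a wired module graph.

    The runner is synchronous; stop and pause requests are injected through
    :meth:`request_stop` / :meth:`request_pause` (typically from the
    ``on_status`` callback) and honored at the documented granularity:
    emergency at the next frame or fluidics tick, smooth at the cycle
    boundary, pause at the ROI boundary.
    """

    OWNER = "task-runner"

    def __init__(self, graph: ModuleGraph, config: ExperimentConfig, on_status=None) -> None:
        self.graph = graph
        self.config = config
        self.on_status = on_status
        self.state = TaskState.STOPPED
        self.state_history: list[TaskState] = [self.state]
        self._emergency = StopToken()
        self._smooth_requested = False
        self._pause_requested = False
        self._resume_requested = False
        self.status_path = Path(config.save_root) / "status.yml"
        self._cycle = 0
        self._roi_id = ""
        self._fluidics_status = ("", 0.0, 0.0)
        self._preanalysis: dict = {}
        self._files: list[Path] = []
        self._schedule: list = []

        self.acq: AcquisitionLogic = self._find_logic(AcquisitionLogic)
        self.focus: FocusLogic = self._find_logic(FocusLogic)
        self.fluidics: FluidicsLogic = self._find_logic(FluidicsLogic)

    def _find_logic(self, cls):
        for obj in self.graph.nodes.values():
            if isinstance(obj, cls):
                return obj
        raise TaskFault(f"setup declares no {cls.__name__} logic module")

    # -- external control ---------------------------------------------------
    def request_stop(self, mode: str = "smooth") -> None:
        """Acknowledge a stop request; a stop while stopped is a no-op."""
        if self.state is TaskState.STOPPED:
            return
        if mode == "emergency":
            self._emergency.request()
        elif mode == "smooth":
            self._smooth_requested = True
            if self.state in (TaskState.RUNNING, TaskState.PAUSING, TaskState.PAUSED):
                self._event(TaskEvent.STOP_SMOOTH)
        else:
            raise ValueError(f"unknown stop mode {mode!r}")

    def request_pause(self) -> None:
        self._pause_requested = True

    def request_resume(self) -> None:
        self._resume_requested = True

    # -- state machine ------------------------------------------------------
    def _event(self, event: TaskEvent) -> None:
        self.state = transition(self.state, event)
        self.state_history.append(self.state)
        if self.graph.log is not None:
            self.graph.log.append("INFO", "task", f"state -> {self.state.value}")

    def _safe_state(self) -> None:
        """Emergency safe state: all lasers off, pump depressurized."""
        self.acq.lasers.all_off()
        self.fluidics.plant.set_pressure(0.0)

    def _check_emergency(self) -> None:
        if self._emergency.requested and self.state is not TaskState.STOPPED:
            self._safe_state()
            self._event(TaskEvent.STOP_EMERGENCY)
            raise TaskFault("emergency stop")

    def _maybe_pause(self) -> None:
        """Honored at ROI boundaries; resume is granted immediately if
        requested (synchronous runner)."""
        if self._pause_requested and self.state is TaskState.RUNNING:
            self._pause_requested = False
            self._event(TaskEvent.PAUSE)
            self._safe_state()
            self._event(TaskEvent.PAUSED)
            self._publish_status()
            if self._emergency.requested:
                self._check_emergency()
            self._event(TaskEvent.RESUME)
            self._event(TaskEvent.RESUMED)
            self._resume_requested = False

    # -- status -------------------------------------------------------------
    def _publish_status(self) -> None:
        step, flow, delivered = self._fluidics_status
        snapshot = StatusSnapshot(
            timestamp_s=self.graph.clock.now,
            task_state=self.state.value,
            cycle=self._cycle,
            roi_id=self._roi_id,
            fluidics_step=step,
            fluidics_flow_ul_min=flow,
            fluidics_delivered_ul=delivered,
            preanalysis=self._preanalysis,
        )
        write_status(snapshot, self.status_path, log=self.graph.log)
        if self.on_status is not None:
            self.on_status(self, snapshot)

    # -- building blocks ----------------------------------------------------
    def _run_sequence(self, key: str, probe: dict | None = None) -> None:
        seq = load_sequence(self.config.sequences[key])
        tray = None
        if probe is not None and probe.get("tray_slot") is not None:
            tray = TrayLayout(slots={probe["name"]: tuple(probe["tray_slot"])})
            for step in seq.steps:
                if step.product == "probe":  # placeholder product bound per cycle
                    step.product = probe["name"]
                    step.tray_slot = tuple(probe["tray_slot"])

        def on_tick(t, flow, delivered):
            self._fluidics_status = (seq.name, flow, delivered)
            self._check_emergency()

        report = self.fluidics.run_sequence(seq, tray=tray, stop=self._emergency, on_tick=on_tick)
        self._check_emergency()
        if not report.completed:
            faults = "; ".join(s.fault_reason for s in report.steps if s.fault)
            self._safe_state()
            if self.state is not TaskState.STOPPED:
                self._event(TaskEvent.STOP_EMERGENCY)
            raise TaskFault(f"fluidics sequence {seq.name!r} failed: {faults or 'aborted'}")
        self._fluidics_status = (seq.name, 0.0, report.total_delivered_ul)

    def _acquire_roi(self, cycle: int, probe_name: str, roi) -> None:
        self._roi_id = roi.id
        self._schedule.append((cycle, roi.id, "acquire"))
        self.acq.stage.move_to(roi.x_um, roi.y_um)
        self.acq.stage.wait_settled()
        self.focus.lasers.set_ir(True)
        setpoint = self.focus.find_reference(below_offset_um=1.5)
        self.focus.lasers.set_ir(False)
        settings = ImagingSettings(
            exposure_ms=self.config.imaging.exposure_ms,
            channels=self.config.imaging.channels,
            n_planes=self.config.imaging.n_planes,
            dz_nm=self.config.imaging.dz_nm,
            z_start_um=setpoint.reference_z_um,
            save_format=self.config.imaging.save_format,
        )
        plan = plan_stack(settings, self.acq.piezo.travel_um)
        stack, events = self.acq.acquire_stack(plan, settings, stop=self._emergency)
        self._check_emergency()
        calib = self.focus.calibration
        metadata = StackMetadata(
            sample_name=self.config.sample_name,
            exposure_ms=settings.exposure_ms,
            laser_lines_nm=[int(line) for line, _ in settings.channels],
            laser_intensities_pct=[float(p) for _, p in settings.channels],
            autofocus_setpoint_v=float(self.focus.setpoint_v),
            autofocus_gains={"kp": 0.6, "ki": 0.2, "kd": 0.0},
            autofocus_slope_v_per_um=float(calib.slope_v_per_um),
            autofocus_precision_nm=float(calib.precision_nm),
            stage_x_um=float(roi.x_um),
            stage_y_um=float(roi.y_um),
            scan_step_nm=float(settings.dz_nm),
            total_z_range_um=float(settings.total_z_range_um),
            cycle=cycle,
            probe=probe_name,
            roi_id=roi.id,
            seed=self.graph.seed,
            timestamp_s=self.graph.clock.now,
        )
        stem_name = format_filename(cycle, probe_name, roi.id, 0).rsplit("_ch", 1)[0]
        stem = Path(self.config.save_root) / stem_name
        paths = write_stack(stem, stack, metadata, settings.save_format)
        self._files.extend(paths)
        pre = preanalyze_stack(stack[:, 0])
        self._preanalysis = {
            "best_focus_plane": pre.best_focus_plane,
            "max_sharpness": max(pre.sharpness),
            "file_stem": stem.name,
        }
        self._publish_status()

    # -- the task -----------------------------------------------------------
    def run(self) -> RunReport:
        """Execute the configured task end to end."""
        errors = validate_config(self.config)
        if errors:
            raise TaskFault("config invalid: " + "; ".join(errors))
        Path(self.config.save_root).mkdir(parents=True, exist_ok=True)
        rois = load_roi_list(self.config.roi_file) if self.config.roi_file else []
        fault = ""
        calib_precision = 0.0
        cycles_done = 0
        self.graph.claim(self.OWNER)
        try:
            self._event(TaskEvent.START)
            self._publish_status()
            # autofocus calibration gates the whole experiment
            if self.config.task in ("him_full", "stack_only", "cycle0_only"):
                calib = self.focus.calibrate()
                calib_precision = calib.precision_nm
                if not calib.valid:
                    raise TaskFault(
                        f"autofocus calibration invalid (precision "
                        f"{calib.precision_nm:.1f} nm, monotonic={calib.monotonic})"
                    )
            self._event(TaskEvent.STARTED)
            self._publish_status()

            if self.config.task in ("him_full", "cycle0_only", "fluidics_only"):
                self._cycle = 0
                self.graph.sample.stain()
                self._run_sequence("cycle0")
                self._publish_status()
            if self.config.task in ("him_full", "cycle0_only", "stack_only"):
                self._cycle = 0
                probe0 = "DAPI"
                for roi in rois:
                    self._check_emergency()
                    self._maybe_pause()
                    self._acquire_roi(0, probe0, roi)
            if self.config.task == "him_full":
                for cycle in range(1, self.config.n_cycles + 1):
                    self._check_emergency()
                    self._cycle = cycle
                    probe = self.config.probes[cycle - 1]
                    self.graph.sample.hybridize(probe["name"])
                    self._run_sequence("hybridization", probe=probe)
                    self._publish_status()
                    for roi in rois:
                        self._check_emergency()
                        self._maybe_pause()
                        self._acquire_roi(cycle, probe["name"], roi)
                    self._run_sequence("bleaching")
                    self.graph.sample.bleach()
                    cycles_done = cycle
                    self._publish_status()
                    if self.state is TaskState.FINISHING:
                        break  # smooth stop: current cycle completed
            if self.state is TaskState.RUNNING:
                self._event(TaskEvent.FINISH)
            if self.state is TaskState.FINISHING:
                self._event(TaskEvent.FINISHED)
            self._publish_status()
            completed = True
        except TaskFault as exc:
            fault = str(exc)
            completed = False
            if self.state is not TaskState.STOPPED:
                self._safe_state()
                self._event(TaskEvent.STOP_EMERGENCY)
            self._publish_status()
        finally:
            self.graph.release(self.OWNER)
        return RunReport(
            completed=completed,
            state_history=list(self.state_history),
            files=[str(p) for p in self._files],
            cycles_done=cycles_done,
            fault=fault,
            schedule=list(self._schedule),
            calibration_precision_nm=calib_precision,
        )
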