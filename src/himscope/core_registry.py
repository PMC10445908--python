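"""Setup configuration, module instantiation and structured logging.

A *setup file* describes one microscope rig: which simulated (or, for real
deployments, driver-backed) devices exist, under which role names, and how
the experimental-logic modules are wired to them. The loader is strict —
unknown models, unknown option keys and dangling connections abort with a
message naming the offending role, so configuration typos surface before an
experiment starts rather than hours into one.

Setup YAML schema (all three top-level keys required)::

    devices:
      <role>: {model: <model-name>, options: {...}}   # options optional
    logic:
      <role>: {logic: <logic-name>, connect: {<connector>: <role>, ...}}
    global:
      field_um: 200.0      # virtual-sample field size
      pixel_um: 0.106      # default camera pixel size (informational)
      seed: 0              # root seed for every device substream
      sample: {...}        # optional generate_sample overrides

Exactly one device with model ``clock.sim`` must be declared; every other
device receives that clock.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from . import hardware_model as hw
from .hardware_model import (
    AutofocusSensorInterface,
    CameraInterface,
    FlowSensorInterface,
    LightSourceInterface,
    SimClock,
    ValveInterface,
    XYStageInterface,
    ZPiezoInterface,
    substream,
)

__all__ = [
    "SetupError",
    "InterfaceError",
    "BusyError",
    "LogRecord",
    "RunLog",
    "SetupConfig",
    "ModuleGraph",
    "load_setup",
    "swap_check",
    "SwapReport",
    "MODEL_REGISTRY",
    "LOGIC_REGISTRY",
]


class SetupError(ValueError):
    """The setup file violates the schema or names unknown entities."""


class InterfaceError(SetupError):
    """A device wired into a connector does not implement its interface."""


class BusyError(RuntimeError):
    """A manual hardware command was issued while a task owns the rig."""


# ---------------------------------------------------------------------------
# Logging
# ---------------------------------------------------------------------------


@dataclass
class LogRecord:
    timestamp_s: float
    level: str
    source: str
    message: str


class RunLog:
    """Line-oriented run log with virtual timestamps.

    Appending never raises — a failed log write must not kill an experiment —
    and :meth:`save` writes one tab-separated record per line, stably sorted
    by timestamp then insertion order.
    """

    def __init__(self, clock: SimClock | None = None) -> None:
        self.records: list[LogRecord] = []
        self._clock = clock

    def append(self, level: str, source: str, message: str, timestamp_s: float | None = None):
        if timestamp_s is None:
            timestamp_s = self._clock.now if self._clock is not None else 0.0
        self.records.append(LogRecord(float(timestamp_s), str(level), str(source), str(message)))

    def log_event(self, record: LogRecord) -> None:
        self.records.append(record)

    def save(self, path) -> None:
        ordered = sorted(self.records, key=lambda r: r.timestamp_s)  # stable
        lines = [
            f"{r.timestamp_s:.6f}\t{r.level}\t{r.source}\t{r.message}" for r in ordered
        ]
        Path(path).write_text("\n".join(lines) + ("\n" if lines else ""), encoding="utf-8")


# ---------------------------------------------------------------------------
# Registries
# ---------------------------------------------------------------------------

# model-name -> (class, preset options merged under user options)
MODEL_REGISTRY: dict[str, tuple[type, dict]] = {
    "clock.sim": (SimClock, {}),
    "camera.sim.ixon512": (
        hw.SimulatedCamera,
        {"sensor_w": 512, "sensor_h": 512, "gain": 4.0, "read_noise": 1.6, "pixel_um": 0.16},
    ),
    "camera.sim.orca2048": (
        hw.SimulatedCamera,
        {"sensor_w": 2048, "sensor_h": 2048, "gain": 0.5, "read_noise": 1.5, "pixel_um": 0.108},
    ),
    "camera.sim": (hw.SimulatedCamera, {}),
    "lasers.sim": (hw.SimulatedLaserBank, {}),
    "filterwheel.sim": (hw.SimulatedFilterWheel, {}),
    "stage.sim.xy": (hw.SimulatedXYStage, {}),
    "piezo.sim.pifoc": (hw.SimulatedPiezo, {}),
    "qpd.sim": (hw.SimulatedQPD, {}),
    "fluidics.sim": (hw.SimulatedFluidics, {}),
}


def _logic_registry():
    # imported lazily to avoid circular imports at module load
    from .acquisition import AcquisitionLogic
    from .fluidics_control import FluidicsLogic
    from .focus_control import FocusLogic
    from .roi_planner import RoiLogic

    return {
        "acquisition": AcquisitionLogic,
        "focus": FocusLogic,
        "fluidics": FluidicsLogic,
        "roi": RoiLogic,
    }


def LOGIC_REGISTRY():  # noqa: N802 - callable registry, resolved lazily
    return _logic_registry()


# ---------------------------------------------------------------------------
# Parsed configuration
# ---------------------------------------------------------------------------


@dataclass
class SetupConfig:
    devices: dict  # role -> (model-name, options)
    logic: dict  # role -> (logic-name, connect map)
    global_opts: dict

    @classmethod
    def from_mapping(cls, doc: Mapping[str, Any]) -> "SetupConfig":
        if not isinstance(doc, Mapping):
            raise SetupError("setup file must be a mapping")
        extra = set(doc) - {"devices", "logic", "global"}
        if extra:
            raise SetupError(f"unknown top-level keys: {sorted(extra)}")
        for key in ("devices", "logic", "global"):
            if key not in doc:
                raise SetupError(f"setup file missing top-level key {key!r}")
        devices: dict = {}
        for role, entry in (doc["devices"] or {}).items():
            if not isinstance(entry, Mapping) or "model" not in entry:
                raise SetupError(f"device {role!r}: entry must be a mapping with a 'model' key")
            bad = set(entry) - {"model", "options"}
            if bad:
                raise SetupError(f"device {role!r}: unknown keys {sorted(bad)}")
            devices[str(role)] = (str(entry["model"]), dict(entry.get("options") or {}))
        logic: dict = {}
        for role, entry in (doc["logic"] or {}).items():
            if role in devices:
                raise SetupError(f"role {role!r} declared as both device and logic")
            if not isinstance(entry, Mapping) or "logic" not in entry:
                raise SetupError(f"logic {role!r}: entry must be a mapping with a 'logic' key")
            bad = set(entry) - {"logic", "connect"}
            if bad:
                raise SetupError(f"logic {role!r}: unknown keys {sorted(bad)}")
            logic[str(role)] = (str(entry["logic"]), dict(entry.get("connect") or {}))
        global_opts = dict(doc["global"] or {})
        bad = set(global_opts) - {"field_um", "pixel_um", "seed", "sample"}
        if bad:
            raise SetupError(f"global: unknown keys {sorted(bad)}")
        seed = global_opts.get("seed", 0)
        if not isinstance(seed, int) or seed < 0:
            raise SetupError("global.seed must be a non-negative integer")
        return cls(devices=devices, logic=logic, global_opts=global_opts)

    @classmethod
    def from_yaml(cls, path) -> "SetupConfig":
        path = Path(path)
        if not path.exists():
            raise SetupError(f"setup file not found: {path}")
        with open(path, "r", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
        return cls.from_mapping(doc or {})


# ---------------------------------------------------------------------------
# Module graph
# ---------------------------------------------------------------------------


@dataclass
class ModuleGraph:
    """Instantiated modules keyed by role, plus the wiring between them."""

    nodes: dict = field(default_factory=dict)
    edges: list = field(default_factory=list)  # (consumer role, provider role)
    clock: SimClock | None = None
    sample: hw.VirtualSample | None = None
    log: RunLog | None = None
    seed: int = 0
    busy_owner: str | None = None

    def node(self, role: str):
        try:
            return self.nodes[role]
        except KeyError:
            raise SetupError(f"no module under role {role!r}") from None

    def attach_sample(self, sample: hw.VirtualSample) -> None:
        """Replace the specimen observed by all sensors (drift re-subscribed)."""
        self.sample = sample
        self.clock.subscribe(sample.advance)

    # -- command arbitration ------------------------------------------------
    def claim(self, owner: str) -> None:
        if self.busy_owner is not None and self.busy_owner != owner:
            raise BusyError(f"hardware busy: owned by {self.busy_owner!r}")
        self.busy_owner = owner

    def release(self, owner: str) -> None:
        if self.busy_owner == owner:
            self.busy_owner = None

    def ensure_available(self, requester: str | None = None) -> None:
        """Reject manual hardware commands while a task owns the rig."""
        if self.busy_owner is not None and self.busy_owner != requester:
            raise BusyError(
                f"rejected: experiment task {self.busy_owner!r} is running; "
                "concurrent hardware commands are disabled"
            )

    def audit_connectors(self) -> None:
        """Re-check every logic node's connectors against the live graph."""
        for role, obj in self.nodes.items():
            required = getattr(type(obj), "required_connectors", None)
            if required is None:
                continue
            for name, iface in required.items():
                provider = getattr(obj, name, None)
                if provider is None:
                    raise SetupError(f"logic {role!r}: connector {name!r} unsatisfied")
                if not isinstance(provider, iface):
                    raise InterfaceError(
                        f"logic {role!r}: connector {name!r} provider does not "
                        f"implement {iface.__name__}"
                    )


def _check_acyclic(edges: list[tuple[str, str]]) -> None:
    adjacency: dict[str, list[str]] = {}
    for a, b in edges:
        adjacency.setdefault(a, []).append(b)
    seen: dict[str, int] = {}  # 1 = in stack, 2 = done

    def visit(node: str, trail: list[str]) -> None:
        state = seen.get(node)
        if state == 1:
            raise SetupError(f"connection cycle: {' -> '.join(trail + [node])}")
        if state == 2:
            return
        seen[node] = 1
        for nxt in adjacency.get(node, []):
            visit(nxt, trail + [node])
        seen[node] = 2

    for node in list(adjacency):
        visit(node, [])


def load_setup(path_or_config) -> ModuleGraph:
    """Instantiate and wire every module declared in a setup file.

    Accepts a filesystem path or a pre-parsed :class:`SetupConfig`. Any
    unsatisfied connector, unknown model or dangling connection aborts with a
    :class:`SetupError` naming the role.
    """
    if isinstance(path_or_config, SetupConfig):
        config = path_or_config
    else:
        config = SetupConfig.from_yaml(path_or_config)

    seed = int(config.global_opts.get("seed", 0))
    graph = ModuleGraph(seed=seed)

    clock_roles = [r for r, (m, _) in config.devices.items() if m == "clock.sim"]
    if len(clock_roles) != 1:
        raise SetupError(
            f"exactly one 'clock.sim' device is required, found {len(clock_roles)}"
        )
    clock = SimClock()
    graph.clock = clock
    graph.log = RunLog(clock)
    graph.nodes[clock_roles[0]] = clock

    # devices
    for role, (model, options) in config.devices.items():
        if model == "clock.sim":
            continue
        if model not in MODEL_REGISTRY:
            raise SetupError(f"device {role!r}: unknown model {model!r}")
        cls, presets = MODEL_REGISTRY[model]
        merged = {**presets, **options}
        allowed = getattr(cls, "allowed_options", frozenset())
        bad = set(merged) - set(allowed)
        if bad:
            raise SetupError(f"device {role!r}: unknown options {sorted(bad)}")
        device = cls(role, clock, substream(seed, role), **merged)
        device.log = graph.log
        graph.nodes[role] = device

    # virtual sample from the global section
    field_um = float(config.global_opts.get("field_um", 200.0))
    sample_opts = dict(config.global_opts.get("sample") or {})
    sample_opts.setdefault("n_emitters", 120)
    sample_opts.setdefault("field_um", field_um)
    sample_opts.setdefault("seed", seed)
    graph.attach_sample(hw.generate_sample(**sample_opts))

    # logic, resolved in dependency order (logic may connect to logic)
    registry = LOGIC_REGISTRY()
    pending = dict(config.logic)
    while pending:
        progressed = False
        for role in list(pending):
            logic_name, connect = pending[role]
            if logic_name not in registry:
                raise SetupError(f"logic {role!r}: unknown logic {logic_name!r}")
            cls = registry[logic_name]
            required = cls.required_connectors
            missing_conn = set(required) - set(connect)
            if missing_conn:
                raise SetupError(
                    f"logic {role!r}: unsatisfied connectors {sorted(missing_conn)}"
                )
            extra = set(connect) - set(required)
            if extra:
                raise SetupError(f"logic {role!r}: unknown connectors {sorted(extra)}")
            targets = connect.values()
            dangling = [t for t in targets if t not in graph.nodes and t not in pending]
            if dangling:
                raise SetupError(
                    f"logic {role!r}: connection targets undeclared role(s) "
                    f"{sorted(dangling)}"
                )
            if any(t in pending for t in targets):
                continue  # provider logic not built yet
            providers = {}
            for name, target in connect.items():
                provider = graph.nodes[target]
                if not isinstance(provider, required[name]):
                    raise InterfaceError(
                        f"logic {role!r}: role {target!r} wired into connector "
                        f"{name!r} does not implement {required[name].__name__}"
                    )
                providers[name] = provider
                graph.edges.append((role, target))
            graph.nodes[role] = cls(role, graph, **providers)
            del pending[role]
            progressed = True
        if not progressed:
            raise SetupError(
                f"logic connection cycle among roles {sorted(pending)}"
            )
    _check_acyclic(graph.edges)
    graph.audit_connectors()
    return graph


# ---------------------------------------------------------------------------
# Hardware-swap transparency check
# ---------------------------------------------------------------------------


@dataclass
class SwapReport:
    """Outcome of loading two configs that differ in one device model."""

    logic_ok: bool
    intrinsic_differences: dict  # role -> {param: (value_a, value_b)}

    @property
    def identical(self) -> bool:
        return self.logic_ok and not self.intrinsic_differences


def swap_check(config_a: SetupConfig, config_b: SetupConfig) -> SwapReport:
    """Verify that swapping one device is transparent to the logic layer.

    Both configurations are loaded, every logic module's scripted exercise is
    run on both graphs, and the report lists the differences — which, for a
    legal swap, are confined to device-intrinsic parameters such as sensor
    dimensions. An incompatible substitution (a device that does not
    implement the role's interface) raises :class:`InterfaceError`.
    """
    graph_a = load_setup(config_a)
    graph_b = load_setup(config_b)
    if set(graph_a.nodes) != set(graph_b.nodes):
        raise SetupError("swap_check: configs declare different role sets")
    for graph in (graph_a, graph_b):
        for role, obj in graph.nodes.items():
            exercise = getattr(obj, "exercise", None)
            if callable(exercise):
                exercise()
    diffs: dict = {}
    for role in graph_a.nodes:
        ia = getattr(graph_a.nodes[role], "intrinsics", lambda: {})()
        ib = getattr(graph_b.nodes[role], "intrinsics", lambda: {})()
        keys = set(ia) | set(ib)
        changed = {k: (ia.get(k), ib.get(k)) for k in sorted(keys) if ia.get(k) != ib.get(k)}
        if changed:
            diffs[role] = changed
    return SwapReport(logic_ok=True, intrinsic_differences=diffs)
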