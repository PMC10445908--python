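"""Synchronized multicolor z-stack acquisition, image writing and filenames.

A stack acquisition steps the piezo through ``n_planes`` positions (250 nm
apart by default) starting at the stack reference position; at each plane
every configured channel is exposed in turn (50 ms default) with exactly one
visible laser line on during the exposure and all lines off before the next
piezo move. The interleaving is per-plane — all channels at each z before
stepping — which minimizes axial drift between channels of the same plane.

Stacks are written one file per channel (multipage along z, 16-bit unsigned)
as TIFF, FITS or a raw little-endian array with a YAML header, plus a YAML
metadata sidecar carrying the sample name, imaging settings, autofocus
parameters, stage position, scan step and total z range.

Filenames follow the multiplexed-acquisition convention
``scan_SSS_PROBE_RRR_ROI_chCC.tif`` (3-digit scan and ROI ordinals, 2-digit
channel); the parser additionally tolerates extra underscore-delimited
tokens inserted by downstream processing (e.g. ``converted_decon``).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
import yaml

from .hardware_model import (
    CameraInterface,
    HardwareError,
    LightSourceInterface,
    StageState,
    XYStageInterface,
    ZPiezoInterface,
)

__all__ = [
    "ImagingSettings",
    "FrameEvent",
    "StackMetadata",
    "FilenameError",
    "plan_stack",
    "write_stack",
    "read_stack",
    "read_metadata",
    "format_filename",
    "parse_filename",
    "ParsedFilename",
    "AcquisitionLogic",
    "audit_events",
    "SAVE_FORMATS",
]

SAVE_FORMATS = ("tiff", "fits", "raw")


@dataclass
class ImagingSettings:
    """One stack's imaging parameters (defaults follow standard practice:
    60 planes 250 nm apart, 50 ms exposure)."""

    exposure_ms: float = 50.0
    channels: list = field(default_factory=lambda: [(561, 20.0), (640, 30.0)])
    n_planes: int = 60
    dz_nm: float = 250.0
    z_start_um: float = 48.5
    save_format: str = "tiff"

    def __post_init__(self) -> None:
        if self.n_planes < 1:
            raise ValueError("n_planes must be >= 1")
        if self.dz_nm <= 0:
            raise ValueError("dz must be > 0")
        if not self.channels:
            raise ValueError("at least one channel is required")
        if self.exposure_ms <= 0:
            raise ValueError("exposure must be > 0")
        if self.save_format not in SAVE_FORMATS:
            raise ValueError(f"save format must be one of {SAVE_FORMATS}")

    @property
    def total_z_range_um(self) -> float:
        return (self.n_planes - 1) * self.dz_nm * 1e-3


@dataclass
class FrameEvent:
    plane: int
    channel: int
    z_um: float
    laser_line_nm: int
    intensity_pct: float
    order: int


@dataclass
class StackMetadata:
    sample_name: str
    exposure_ms: float
    laser_lines_nm: list
    laser_intensities_pct: list
    autofocus_setpoint_v: float
    autofocus_gains: dict
    autofocus_slope_v_per_um: float
    autofocus_precision_nm: float
    stage_x_um: float
    stage_y_um: float
    scan_step_nm: float
    total_z_range_um: float
    cycle: int
    probe: str
    roi_id: str
    seed: int
    timestamp_s: float

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def plan_stack(settings: ImagingSettings, piezo_travel=(0.0, 100.0)) -> list[FrameEvent]:
    """Enumerate the acquisition plan: plane-major, channels interleaved.

    Exactly ``n_planes * n_channels`` events; the piezo moves ``n_planes - 1``
    times because all channels share each plane's position.
    """
    lo, hi = piezo_travel
    z_end = settings.z_start_um + settings.total_z_range_um
    if settings.z_start_um < lo or z_end > hi:
        raise HardwareError(
            f"stack z range {settings.z_start_um:.2f}–{z_end:.2f} µm outside piezo "
            f"travel {lo}–{hi} µm"
        )
    events: list[FrameEvent] = []
    order = 0
    for plane in range(settings.n_planes):
        z = settings.z_start_um + plane * settings.dz_nm * 1e-3
        for channel, (line, pct) in enumerate(settings.channels):
            events.append(FrameEvent(plane, channel, z, int(line), float(pct), order))
            order += 1
    return events


def audit_events(event_log: list[dict]) -> list[str]:
    """Synchronization audit of an acquisition event log.

    Checks that every camera trigger happened with a settled stage and
    exactly one visible laser on, that lasers are off between planes, and
    that z is nondecreasing. Returns violation strings (empty = clean).
    """
    violations = []
    z_last = -np.inf
    for i, ev in enumerate(event_log):
        if ev["kind"] == "trigger":
            if not ev["settled"]:
                violations.append(f"event {i}: trigger with unsettled stage")
            if ev["n_lasers_on"] != 1:
                violations.append(f"event {i}: {ev['n_lasers_on']} visible lasers on at trigger")
        elif ev["kind"] == "move_z":
            if ev["n_lasers_on"] != 0:
                violations.append(f"event {i}: laser on during piezo move")
            if ev["z_um"] < z_last - 1e-9:
                violations.append(f"event {i}: z not nondecreasing")
            z_last = ev["z_um"]
    return violations


# ---------------------------------------------------------------------------
# Filename convention
# ---------------------------------------------------------------------------


class FilenameError(ValueError):
    """A filename does not follow the scan/probe/ROI/channel convention."""


@dataclass
class ParsedFilename:
    scan: int
    probe: str
    roi_id: str
    channel: int
    extension: str = "tif"


_FILENAME_RE = re.compile(
    r"^scan_(\d{3})_([^_]+)_(\d{3})_ROI(?:_[^_]+)*?_ch(\d{2})\.(\w+)$"
)


def format_filename(scan: int, probe: str, roi_id, channel: int, extension: str = "tif") -> str:
    """``scan_SSS_PROBE_RRR_ROI_chCC.ext`` with zero-padded ordinals."""
    if scan < 0 or channel < 0:
        raise FilenameError("scan and channel indices must be >= 0")
    if "_" in probe or not probe:
        raise FilenameError(f"probe token must be nonempty and underscore-free: {probe!r}")
    roi_num = int(roi_id)
    return f"scan_{scan:03d}_{probe}_{roi_num:03d}_ROI_ch{channel:02d}.{extension}"


def parse_filename(name: str) -> ParsedFilename:
    """Invert :func:`format_filename`; tolerates extra tokens before chCC."""
    m = _FILENAME_RE.match(Path(name).name)
    if m is None:
        raise FilenameError(f"filename does not match the scan/probe/ROI convention: {name!r}")
    return ParsedFilename(
        scan=int(m.group(1)),
        probe=m.group(2),
        roi_id=m.group(3),
        channel=int(m.group(4)),
        extension=m.group(5),
    )


# ---------------------------------------------------------------------------
# Writing and reading stacks
# ---------------------------------------------------------------------------


def _fits_header(shape: tuple) -> bytes:
    """Minimal FITS primary-HDU header for a 16-bit unsigned z-stack."""
    n_planes, h, w = shape
    cards = [
        ("SIMPLE", "T", "conforms to FITS standard"),
        ("BITPIX", "16", "16-bit signed with BZERO offset"),
        ("NAXIS", "3", ""),
        ("NAXIS1", str(w), "image width"),
        ("NAXIS2", str(h), "image height"),
        ("NAXIS3", str(n_planes), "z planes"),
        ("BZERO", "32768", "offset for unsigned 16-bit"),
        ("BSCALE", "1", ""),
    ]
    lines = []
    for key, value, comment in cards:
        text = f"{key:<8}= {value:>20}"
        if comment:
            text += f" / {comment}"
        lines.append(text[:80].ljust(80))
    lines.append("END".ljust(80))
    block = "".join(lines)
    pad = (2880 - len(block) % 2880) % 2880
    return (block + " " * pad).encode("ascii")


def _write_fits(path: Path, stack3d: np.ndarray) -> None:
    data = (stack3d.astype(np.int32) - 32768).astype(">i2")
    raw = data.tobytes()
    pad = (2880 - len(raw) % 2880) % 2880
    path.write_bytes(_fits_header(stack3d.shape) + raw + b"\x00" * pad)


def _read_fits(path: Path) -> np.ndarray:
    blob = path.read_bytes()
    header = {}
    offset = 0
    while True:
        card = blob[offset : offset + 80].decode("ascii")
        offset += 80
        key = card[:8].strip()
        if key == "END":
            break
        if "=" in card:
            header[key] = card.split("=", 1)[1].split("/", 1)[0].strip()
    offset = ((offset + 2879) // 2880) * 2880
    shape = (int(header["NAXIS3"]), int(header["NAXIS2"]), int(header["NAXIS1"]))
    count = shape[0] * shape[1] * shape[2]
    data = np.frombuffer(blob, dtype=">i2", count=count, offset=offset).astype(np.int32)
    return (data + int(header.get("BZERO", 0))).astype(np.uint16).reshape(shape)


def write_stack(path_stem, stack: np.ndarray, metadata: StackMetadata, save_format: str = "tiff"):
    """Write one file per channel plus the YAML metadata sidecar.

    ``stack`` has shape (planes, channels, h, w), dtype uint16. Returns the
    list of written image paths. The sidecar is ``<stem>_meta.yml``.
    """
    if stack.size == 0:
        raise ValueError("refusing to write an empty stack")
    if save_format not in SAVE_FORMATS:
        raise ValueError(f"unsupported save format {save_format!r}")
    stem = Path(path_stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    n_planes, n_channels = stack.shape[:2]
    paths = []
    for c in range(n_channels):
        planes = np.ascontiguousarray(stack[:, c])
        if save_format == "tiff":
            path = stem.parent / f"{stem.name}_ch{c:02d}.tif"
            tifffile.imwrite(path, planes, photometric="minisblack")
        elif save_format == "fits":
            path = stem.parent / f"{stem.name}_ch{c:02d}.fits"
            _write_fits(path, planes)
        else:
            path = stem.parent / f"{stem.name}_ch{c:02d}.bin"
            path.write_bytes(planes.astype("<u2").tobytes())
            header = {
                "dtype": "uint16",
                "byteorder": "little",
                "shape": list(planes.shape),
            }
            path.with_suffix(".bin.yml").write_text(
                yaml.safe_dump(header, sort_keys=False), encoding="utf-8"
            )
        paths.append(path)
    sidecar = stem.parent / f"{stem.name}_meta.yml"
    sidecar.write_text(yaml.safe_dump(metadata.to_dict(), sort_keys=False), encoding="utf-8")
    return paths


def read_stack(path) -> np.ndarray:
    """Read back one channel file (planes, h, w) written by :func:`write_stack`."""
    path = Path(path)
    if path.suffix == ".tif":
        return tifffile.imread(path)
    if path.suffix == ".fits":
        return _read_fits(path)
    if path.suffix == ".bin":
        header = yaml.safe_load(path.with_suffix(".bin.yml").read_text(encoding="utf-8"))
        data = np.frombuffer(path.read_bytes(), dtype="<u2")
        return data.reshape(header["shape"]).astype(np.uint16)
    raise ValueError(f"unknown stack extension {path.suffix!r}")


def read_metadata(stem_or_sidecar) -> dict:
    path = Path(stem_or_sidecar)
    if path.suffix not in (".yml", ".yaml"):
        path = path.parent / f"{path.name}_meta.yml"
    return yaml.safe_load(path.read_text(encoding="utf-8"))


# ---------------------------------------------------------------------------
# Wired logic module
# ---------------------------------------------------------------------------


class AcquisitionLogic:
    """Imaging toolbox bound to camera + piezo + laser bank (+ XY stage)."""

    required_connectors = {
        "camera": CameraInterface,
        "piezo": ZPiezoInterface,
        "lasers": LightSourceInterface,
        "stage": XYStageInterface,
    }

    def __init__(self, role, graph, camera, piezo, lasers, stage) -> None:
        self.role = role
        self.graph = graph
        self.camera = camera
        self.piezo = piezo
        self.lasers = lasers
        self.stage = stage

    def _stage_state(self) -> StageState:
        return StageState(
            x_um=self.stage.x_um,
            y_um=self.stage.y_um,
            piezo_z_um=self.piezo.position_um,
            settled=self.stage.settled and self.piezo.settled,
        )

    def acquire_stack(self, plan: list[FrameEvent], settings: ImagingSettings, stop=None):
        """Execute a stack plan with laser/camera/piezo synchronization.

        Returns ``(stack, event_log)`` with stack shape
        (planes, channels, h, w) uint16. The event log records every piezo
        move and camera trigger with the laser and settle state at that
        instant, for post-hoc synchronization audits. A stop token aborts
        between frames with all lasers off.
        """
        cam = self.camera.settings
        n_channels = len(settings.channels)
        n_planes = settings.n_planes if plan else 0
        stack = np.zeros((n_planes, n_channels, cam.sensor_h, cam.sensor_w), dtype=np.uint16)
        events: list[dict] = []
        clock = self.graph.clock
        self.camera.set_exposure(settings.exposure_ms)
        aborted = False
        current_plane = None
        for ev in plan:
            if stop is not None and stop.requested:
                aborted = True
                break
            if ev.plane != current_plane:
                bank = self.lasers.state
                events.append(
                    {
                        "kind": "move_z",
                        "t": clock.now,
                        "z_um": ev.z_um,
                        "n_lasers_on": len(bank.active_lines()),
                    }
                )
                self.piezo.move_to(ev.z_um)
                self.piezo.wait_settled()
                current_plane = ev.plane
            self.lasers.set_intensity(ev.laser_line_nm, ev.intensity_pct)
            state = self._stage_state()
            bank = self.lasers.state
            events.append(
                {
                    "kind": "trigger",
                    "t": clock.now,
                    "plane": ev.plane,
                    "channel": ev.channel,
                    "z_um": state.piezo_z_um,
                    "settled": state.settled,
                    "n_lasers_on": len(bank.active_lines()),
                }
            )
            if not state.settled:
                self.lasers.set_intensity(ev.laser_line_nm, 0.0)
                raise HardwareError("frame trigger with unsettled hardware; aborting stack")
            frame = self.camera.snap(self.graph.sample, state, bank)
            clock.advance(settings.exposure_ms * 1e-3)
            self.lasers.set_intensity(ev.laser_line_nm, 0.0)
            stack[ev.plane, ev.channel] = frame
        if aborted:
            for line, _ in settings.channels:
                self.lasers.set_intensity(line, 0.0)
        return stack, events

    def exercise(self) -> dict:
        """Scripted mini-acquisition used by hardware-swap checks."""
        settings = ImagingSettings(n_planes=2, channels=[(561, 10.0)], z_start_um=50.0)
        plan = plan_stack(settings, self.piezo.travel_um)
        stack, events = self.acquire_stack(plan, settings)
        return {"n_frames": len([e for e in events if e["kind"] == "trigger"]),
                "frame_shape": stack.shape[2:]}
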