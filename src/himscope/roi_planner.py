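"""ROI lists, snake-ordered stage mosaics and region interpolation.

An ROI is a named stage position revisited every acquisition cycle. Mosaics
are built from a center and a tile count; alternatively two corners of a
region can be given and the minimal tile grid covering it is interpolated.
Tiles are visited in a boustrophedon (snake) order — alternating direction
on successive rows — so consecutive stage moves are always one pitch long.
ROI lists persist as YAML.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import yaml

from .hardware_model import XY_TRAVEL_UM, XYStageInterface

__all__ = [
    "ROI",
    "MosaicSpec",
    "RoiListError",
    "build_mosaic",
    "interpolate_region",
    "save_roi_list",
    "load_roi_list",
    "RoiLogic",
]


class RoiListError(ValueError):
    """An ROI list (in memory or on disk) violates its invariants."""


@dataclass
class ROI:
    id: str  # zero-padded ordinal, e.g. "001"
    x_um: float
    y_um: float
    z_um: float | None = None


@dataclass
class MosaicSpec:
    """Snake mosaic: center, rows x cols tiles, square FOV, overlap fraction."""

    center_x_um: float
    center_y_um: float
    n_rows: int
    n_cols: int
    fov_um: float
    overlap: float = 0.0

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("mosaic needs n_rows, n_cols >= 1")
        if not 0.0 <= self.overlap < 1.0:
            raise ValueError("overlap fraction must be in [0, 1)")
        if self.fov_um <= 0:
            raise ValueError("fov must be > 0")

    @property
    def pitch_um(self) -> float:
        return self.fov_um * (1.0 - self.overlap)


def _snake_grid(x_centers, y_centers, travel_um: float) -> list[ROI]:
    rois: list[ROI] = []
    ordinal = 1
    for r, y in enumerate(y_centers):
        cols = x_centers if r % 2 == 0 else list(reversed(x_centers))
        for x in cols:
            if abs(x) > travel_um or abs(y) > travel_um:
                raise RoiListError(
                    f"tile at ({x:.1f}, {y:.1f}) µm exceeds stage travel ±{travel_um} µm"
                )
            rois.append(ROI(id=f"{ordinal:03d}", x_um=float(x), y_um=float(y)))
            ordinal += 1
    return rois


def build_mosaic(spec: MosaicSpec, travel_um: float = XY_TRAVEL_UM) -> list[ROI]:
    """Tile grid centered on the spec center, visited in snake order.

    The snake starts at the top-left tile (minimal x and y) moving toward
    increasing x, and ids are assigned 001, 002, ... in visit order.
    """
    pitch = spec.pitch_um
    xs = [spec.center_x_um + (c - (spec.n_cols - 1) / 2.0) * pitch for c in range(spec.n_cols)]
    ys = [spec.center_y_um + (r - (spec.n_rows - 1) / 2.0) * pitch for r in range(spec.n_rows)]
    return _snake_grid(xs, ys, travel_um)


def interpolate_region(
    corner_a: tuple,
    corner_b: tuple,
    fov_um: float,
    overlap: float = 0.0,
    travel_um: float = XY_TRAVEL_UM,
) -> list[ROI]:
    """Minimal snake grid covering the rectangle spanned by two corners.

    Per axis the tile count is ``ceil((span - fov)/pitch) + 1`` (minimum 1);
    the grid is centered on the region so slack is split between both edges.
    """
    if fov_um <= 0:
        raise ValueError("fov must be > 0")
    if not 0.0 <= overlap < 1.0:
        raise ValueError("overlap fraction must be in [0, 1)")
    if tuple(corner_a) == tuple(corner_b):
        raise ValueError("region corners must be distinct")
    pitch = fov_um * (1.0 - overlap)
    counts = []
    centers = []
    for lo, hi in ((min(corner_a[i], corner_b[i]), max(corner_a[i], corner_b[i])) for i in (0, 1)):
        span = hi - lo
        n = max(1, math.ceil((span - fov_um) / pitch - 1e-9) + 1)
        counts.append(n)
        mid = (lo + hi) / 2.0
        centers.append([mid + (k - (n - 1) / 2.0) * pitch for k in range(n)])
    return _snake_grid(centers[0], centers[1], travel_um)


# ---------------------------------------------------------------------------
# YAML persistence
# ---------------------------------------------------------------------------


def _validate_list(rois: list[ROI], travel_um: float) -> None:
    seen: set[str] = set()
    for roi in rois:
        if roi.id in seen:
            raise RoiListError(f"duplicate ROI id {roi.id!r}")
        seen.add(roi.id)
        if abs(roi.x_um) > travel_um or abs(roi.y_um) > travel_um:
            raise RoiListError(f"ROI {roi.id!r} outside stage travel ±{travel_um} µm")


def save_roi_list(rois: list[ROI], path, travel_um: float = XY_TRAVEL_UM) -> None:
    _validate_list(rois, travel_um)
    doc = []
    for roi in rois:
        entry = {"id": roi.id, "x_um": float(roi.x_um), "y_um": float(roi.y_um)}
        if roi.z_um is not None:
            entry["z_um"] = float(roi.z_um)
        doc.append(entry)
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False), encoding="utf-8")


def load_roi_list(path, travel_um: float = XY_TRAVEL_UM) -> list[ROI]:
    path = Path(path)
    if not path.exists():
        raise RoiListError(f"ROI file not found: {path}")
    doc = yaml.safe_load(path.read_text(encoding="utf-8"))
    if doc is None:
        return []
    if not isinstance(doc, list):
        raise RoiListError("ROI file must be a YAML sequence of mappings")
    rois: list[ROI] = []
    for i, entry in enumerate(doc):
        if not isinstance(entry, dict):
            raise RoiListError(f"ROI entry {i}: not a mapping")
        missing = {"id", "x_um", "y_um"} - set(entry)
        if missing:
            raise RoiListError(f"ROI entry {i}: missing fields {sorted(missing)}")
        extra = set(entry) - {"id", "x_um", "y_um", "z_um"}
        if extra:
            raise RoiListError(f"ROI entry {i}: unknown fields {sorted(extra)}")
        rois.append(
            ROI(
                id=str(entry["id"]),
                x_um=float(entry["x_um"]),
                y_um=float(entry["y_um"]),
                z_um=float(entry["z_um"]) if "z_um" in entry else None,
            )
        )
    _validate_list(rois, travel_um)
    return rois


class RoiLogic:
    """ROI selector bound to the wired XY stage."""

    required_connectors = {"stage": XYStageInterface}

    def __init__(self, role, graph, stage) -> None:
        self.role = role
        self.graph = graph
        self.stage = stage

    def goto(self, roi: ROI) -> None:
        self.stage.move_to(roi.x_um, roi.y_um)
        self.stage.wait_settled()

    def mosaic(self, spec: MosaicSpec) -> list[ROI]:
        return build_mosaic(spec, travel_um=getattr(self.stage, "travel_um", XY_TRAVEL_UM))

    def exercise(self) -> dict:
        self.stage.move_to(10.0, -10.0)
        self.stage.wait_settled()
        return {"settled": self.stage.settled}
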