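"""Shared fixtures: small simulated rigs and toy experiment configurations.

All fixtures build their inputs programmatically; tests use a 64x64 camera
and short injection steps so full multi-cycle experiments run in seconds.
"""

from __future__ import annotations

import copy
from pathlib import Path

import pytest
import yaml

from himscope import SetupConfig, load_setup
from himscope.acquisition import ImagingSettings
from himscope.task_engine import ExperimentConfig


def small_setup_doc(seed: int = 0, drift_rate_nm_s: float = 0.0, qpd_noise_v: float = 0.005):
    """Setup document for a fully simulated rig with a small, fast camera."""
    return {
        "devices": {
            "clk": {"model": "clock.sim"},
            "cam": {
                "model": "camera.sim",
                "options": {"sensor_w": 64, "sensor_h": 64, "pixel_um": 0.16},
            },
            "ls": {"model": "lasers.sim"},
            "st": {"model": "stage.sim.xy"},
            "pz": {"model": "piezo.sim.pifoc"},
            "qpd": {"model": "qpd.sim", "options": {"noise_v": qpd_noise_v}},
            "flu": {"model": "fluidics.sim"},
        },
        "logic": {
            "acq": {
                "logic": "acquisition",
                "connect": {"camera": "cam", "piezo": "pz", "lasers": "ls", "stage": "st"},
            },
            "focus": {"logic": "focus", "connect": {"qpd": "qpd", "piezo": "pz", "lasers": "ls"}},
            "fluidics": {"logic": "fluidics", "connect": {"plant": "flu"}},
            "roi": {"logic": "roi", "connect": {"stage": "st"}},
        },
        "global": {
            "field_um": 200.0,
            "pixel_um": 0.16,
            "seed": seed,
            "sample": {
                "n_emitters": 40,
                "n_probes": 2,
                "drift_rate_nm_s": drift_rate_nm_s,
                "diffusion_nm2_s": 0.0,
            },
        },
    }


def build_graph(seed: int = 0, **kwargs):
    return load_setup(SetupConfig.from_mapping(small_setup_doc(seed=seed, **kwargs)))


@pytest.fixture
def graph():
    return build_graph()


def write_toy_inputs(root: Path) -> dict:
    """Write short injection sequences and a 3-ROI list; return their paths."""
    root.mkdir(parents=True, exist_ok=True)
    seqs = {
        "cycle0": {
            "name": "cycle-0",
            "steps": [
                {"product": "DAPI-stain", "valve": 2, "volume_ul": 20.0,
                 "flow_ul_min": 250.0, "incubation_s": 5.0},
                {"product": "fiducial-probe", "valve": 3, "volume_ul": 20.0,
                 "flow_ul_min": 250.0, "incubation_s": 5.0},
            ],
        },
        "hybridization": {
            "name": "hybridization",
            "steps": [
                {"product": "probe", "valve": 5, "volume_ul": 20.0,
                 "flow_ul_min": 250.0, "incubation_s": 5.0},
                {"product": "wash-buffer", "valve": 1, "volume_ul": 20.0,
                 "flow_ul_min": 300.0, "incubation_s": 0.0},
            ],
        },
        "bleaching": {
            "name": "bleaching",
            "steps": [
                {"product": "bleach-solution", "valve": 6, "volume_ul": 20.0,
                 "flow_ul_min": 250.0, "incubation_s": 5.0},
            ],
        },
    }
    paths = {}
    for key, doc in seqs.items():
        path = root / f"seq_{key}.yml"
        path.write_text(yaml.safe_dump(doc, sort_keys=False), encoding="utf-8")
        paths[key] = str(path)
    roi_path = root / "rois.yml"
    roi_path.write_text(
        yaml.safe_dump(
            [
                {"id": "001", "x_um": 0.0, "y_um": 0.0},
                {"id": "002", "x_um": 90.0, "y_um": 0.0},
                {"id": "003", "x_um": 90.0, "y_um": 90.0},
            ]
        ),
        encoding="utf-8",
    )
    paths["rois"] = str(roi_path)
    return paths


def toy_experiment_config(tmp_path: Path, n_cycles: int = 2, seed: int = 0) -> ExperimentConfig:
    """2 cycles x 3 ROIs x 2 channels x 5 planes against short chemistry."""
    paths = write_toy_inputs(tmp_path / "inputs")
    return ExperimentConfig(
        task="him_full",
        sample_name="toy-sample",
        save_root=str(tmp_path / "run"),
        imaging=ImagingSettings(
            exposure_ms=50.0,
            channels=[(561, 20.0), (640, 30.0)],
            n_planes=5,
            dz_nm=250.0,
            z_start_um=48.5,
            save_format="tiff",
        ),
        roi_file=paths["rois"],
        sequences={k: paths[k] for k in ("cycle0", "hybridization", "bleaching")},
        probes=[{"cycle": c + 1, "name": f"RT{c + 1:02d}", "tray_slot": [1, c + 1, 1]}
                for c in range(n_cycles)],
        n_cycles=n_cycles,
        seed=seed,
    )


@pytest.fixture
def toy_config(tmp_path):
    return toy_experiment_config(tmp_path)
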