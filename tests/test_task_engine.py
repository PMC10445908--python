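"""State machine soundness, config validation and end-to-end toy experiments."""

import hashlib
from collections import deque
from pathlib import Path

import numpy as np
import pytest
import yaml

from himscope.core_registry import BusyError
from himscope.acquisition import parse_filename
from himscope.task_engine import (
    TRANSITIONS,
    ExperimentConfig,
    StatusSnapshot,
    TaskEvent,
    TaskRunner,
    TaskState,
    TransitionError,
    preanalyze_stack,
    read_status,
    transition,
    validate_config,
    write_status,
)

from conftest import build_graph, toy_experiment_config


class TestStateMachine:
    def test_start_from_stopped_enters_starting(self):
        assert transition(TaskState.STOPPED, TaskEvent.START) is TaskState.STARTING

    def test_invalid_event_rejected_state_unchanged(self):
        state = TaskState.RUNNING
        with pytest.raises(TransitionError):
            transition(state, TaskEvent.RESUME)
        assert state is TaskState.RUNNING

    def test_every_state_reaches_stopped_by_bfs(self):
        for origin in TaskState:
            frontier = deque([(origin, 0)])
            seen = {origin}
            reached = None
            while frontier:
                state, depth = frontier.popleft()
                if state is TaskState.STOPPED:
                    reached = depth
                    break
                for (s, e), nxt in TRANSITIONS.items():
                    if s is state and nxt not in seen:
                        seen.add(nxt)
                        frontier.append((nxt, depth + 1))
            assert reached is not None, f"stopped unreachable from {origin}"

    def test_emergency_reaches_stopped_within_two_transitions(self):
        for origin in TaskState:
            if origin is TaskState.STOPPED:
                continue
            assert transition(origin, TaskEvent.STOP_EMERGENCY) is TaskState.STOPPED

    def test_no_event_sequence_leaves_the_state_set(self):
        for (state, event), nxt in TRANSITIONS.items():
            assert isinstance(nxt, TaskState)


class TestConfigValidation:
    def test_complete_him_config_is_valid(self, toy_config):
        assert validate_config(toy_config) == []

    def test_missing_roi_file_named(self, toy_config):
        toy_config.roi_file = None
        errors = validate_config(toy_config)
        assert any("roi_file" in e for e in errors)

    def test_zero_dz_named(self, toy_config):
        toy_config.imaging.dz_nm = 0.0
        errors = validate_config(toy_config)
        assert any(e.startswith("dz") for e in errors)

    def test_probe_list_must_match_cycle_count(self, toy_config):
        toy_config.probes = toy_config.probes[:1]
        errors = validate_config(toy_config)
        assert any("probes" in e for e in errors)

    def test_config_roundtrips_through_yaml(self, toy_config, tmp_path):
        path = tmp_path / "cfg.yml"
        toy_config.to_yaml(path)
        loaded = ExperimentConfig.from_yaml(path)
        assert loaded == toy_config


def run_toy(tmp_path, seed=0, n_cycles=2, on_status=None):
    config = toy_experiment_config(tmp_path, n_cycles=n_cycles, seed=seed)
    graph = build_graph(seed=seed)
    runner = TaskRunner(graph, config, on_status=on_status)
    report = runner.run()
    return graph, runner, report, config


class TestHimRun:
    def test_file_census_and_schedule_match_expected(self, tmp_path):
        graph, runner, report, config = run_toy(tmp_path)
        assert report.completed and report.cycles_done == 2
        run_dir = Path(config.save_root)
        cycle_files = sorted(run_dir.glob("scan_*_RT*_ch*.tif"))
        assert len(cycle_files) == 2 * 3 * 2  # cycles x ROIs x channels
        cycle0_files = sorted(run_dir.glob("scan_000_DAPI_*_ch*.tif"))
        assert len(cycle0_files) == 3 * 2
        for f in cycle_files + cycle0_files:
            parsed = parse_filename(f.name)  # all names round-trip the codec
            assert parsed.roi_id in {"001", "002", "003"}
        expected_schedule = [(0, f"{r:03d}", "acquire") for r in (1, 2, 3)]
        for cycle in (1, 2):
            expected_schedule += [(cycle, f"{r:03d}", "acquire") for r in (1, 2, 3)]
        assert report.schedule == expected_schedule
        assert report.state_history[-1] is TaskState.STOPPED

    def test_zero_cycles_yields_only_cycle0_outputs(self, tmp_path):
        graph, runner, report, config = run_toy(tmp_path, n_cycles=0)
        assert report.completed
        files = sorted(Path(config.save_root).glob("scan_*_ch*.tif"))
        assert files and all(f.name.startswith("scan_000_DAPI") for f in files)

    def test_same_seed_reproduces_file_hashes_and_status_sequence(self, tmp_path):
        def digest(tree: Path):
            out = {}
            for f in sorted(tree.glob("scan_*_ch*")):
                out[f.name] = hashlib.sha256(f.read_bytes()).hexdigest()
            return out

        snapshots = [[], []]
        for i in range(2):
            sub = tmp_path / f"rep{i}"
            graph, runner, report, config = run_toy(
                sub, seed=5, on_status=lambda r, s, i=i: snapshots[i].append(s.to_dict())
            )
            assert report.completed
        assert digest(tmp_path / "rep0" / "run") == digest(tmp_path / "rep1" / "run")
        assert snapshots[0] == snapshots[1]

    def test_metadata_sidecar_reflects_stack_geometry(self, tmp_path):
        graph, runner, report, config = run_toy(tmp_path, n_cycles=1)
        sidecars = sorted(Path(config.save_root).glob("*_meta.yml"))
        assert sidecars
        doc = yaml.safe_load(sidecars[0].read_text())
        assert doc["scan_step_nm"] == 250.0
        assert doc["total_z_range_um"] == pytest.approx((5 - 1) * 0.250)
        assert doc["exposure_ms"] == 50.0


class TestStops:
    def test_smooth_stop_completes_current_cycle_only(self, tmp_path):
        def on_status(runner, snapshot):
            if snapshot.cycle == 1 and snapshot.roi_id == "001" and snapshot.preanalysis:
                runner.request_stop("smooth")

        config = toy_experiment_config(tmp_path, n_cycles=3)
        graph = build_graph()
        runner = TaskRunner(graph, config, on_status=on_status)
        report = runner.run()
        assert report.completed and report.cycles_done == 1
        files = sorted(Path(config.save_root).glob("scan_*_RT*_ch*.tif"))
        assert len(files) == 1 * 3 * 2  # cycle 1 finished (incl. all its ROIs)
        assert all(parse_filename(f.name).scan == 1 for f in files)
        # bleaching of the completed cycle ran before stopping
        bleach_msgs = [r for r in graph.log.records if "bleach" in r.message]
        assert bleach_msgs
        assert runner.state is TaskState.STOPPED

    def test_emergency_stop_halts_and_safes_hardware(self, tmp_path):
        def on_status(runner, snapshot):
            if snapshot.cycle == 1 and snapshot.roi_id == "002" and snapshot.preanalysis:
                runner.request_stop("emergency")

        config = toy_experiment_config(tmp_path, n_cycles=2)
        graph = build_graph()
        runner = TaskRunner(graph, config, on_status=on_status)
        report = runner.run()
        assert not report.completed and "emergency" in report.fault
        files = sorted(Path(config.save_root).glob("scan_001_RT01_*_ch*.tif"))
        rois = {parse_filename(f.name).roi_id for f in files}
        assert rois == {"001", "002"}  # ROI 3 never acquired
        lasers = graph.node("ls").state
        assert all(v == 0.0 for v in lasers.intensity.values()) and not lasers.ir_785_on
        assert graph.node("flu").state.pressure_mbar == 0.0
        assert runner.state is TaskState.STOPPED

    def test_stop_while_stopped_is_a_noop(self, tmp_path):
        config = toy_experiment_config(tmp_path)
        runner = TaskRunner(build_graph(), config)
        runner.request_stop("smooth")
        runner.request_stop("emergency")
        assert runner.state is TaskState.STOPPED

    def test_pause_resumes_at_roi_boundary(self, tmp_path):
        paused_states = []

        def on_status(runner, snapshot):
            if snapshot.cycle == 1 and snapshot.roi_id == "001" and snapshot.preanalysis \
                    and TaskState.PAUSED not in runner.state_history:
                runner.request_pause()
            paused_states.append(snapshot.task_state)

        config = toy_experiment_config(tmp_path, n_cycles=1)
        runner = TaskRunner(build_graph(), config, on_status=on_status)
        report = runner.run()
        assert report.completed
        assert TaskState.PAUSED in runner.state_history
        assert "paused" in paused_states


class TestStatusFile:
    def test_snapshot_file_always_parses_during_run(self, tmp_path):
        cycles = []

        def on_status(runner, snapshot):
            doc = read_status(runner.status_path)  # poll mid-run
            assert isinstance(doc, dict)
            assert {"cycle", "task_state", "fluidics_step"} <= set(doc)
            cycles.append(doc["cycle"])

        graph, runner, report, config = run_toy(tmp_path, on_status=on_status)
        assert report.completed
        assert cycles == sorted(cycles)  # nondecreasing cycle numbers

    def test_write_failure_is_swallowed(self, tmp_path):
        snap = StatusSnapshot(0.0, "running", 1)
        write_status(snap, tmp_path / "missing-dir" / "status.yml")  # no raise

    def test_hardware_commands_rejected_while_task_runs(self, tmp_path):
        def on_status(runner, snapshot):
            with pytest.raises(BusyError):
                runner.graph.ensure_available("user-gui")

        graph, runner, report, config = run_toy(tmp_path, n_cycles=0,
                                                on_status=on_status)
        assert report.completed
        graph.ensure_available("user-gui")  # released after the run


class TestPreAnalysis:
    def test_uniform_stack_ties_break_to_plane_zero(self):
        stack = np.full((4, 8, 8), 7, dtype=np.uint16)
        pre = preanalyze_stack(stack)
        assert pre.best_focus_plane == 0
        assert len(set(pre.sharpness)) == 1

    def test_projection_equals_elementwise_max_oracle(self):
        rng = np.random.default_rng(3)
        stack = rng.integers(0, 1000, (5, 6, 6), dtype=np.uint16)
        pre = preanalyze_stack(stack)
        oracle = stack[0]
        for plane in stack[1:]:
            oracle = np.maximum(oracle, plane)
        np.testing.assert_array_equal(pre.max_projection, oracle)

    def test_best_focus_near_true_focal_plane_of_simulated_stack(self):
        from himscope.acquisition import ImagingSettings, plan_stack

        graph = build_graph(seed=2)
        acq = graph.node("acq")
        focus = graph.node("focus")
        sample = graph.sample
        idx = int(np.flatnonzero(sample.is_fiducial)[0])
        sample.z_um[idx] = 0.0  # emitter exactly on the focal surface
        sample.brightness[idx] = 400.0
        acq.stage.move_to(sample.x_um[idx], sample.y_um[idx])
        acq.stage.wait_settled()
        focus.calibrate()
        sp = focus.find_reference(below_offset_um=1.0)
        settings_ = ImagingSettings(n_planes=9, dz_nm=250.0, channels=[(561, 50.0)],
                                    z_start_um=sp.reference_z_um)
        stack, _ = acq.acquire_stack(plan_stack(settings_), settings_)
        pre = preanalyze_stack(stack[:, 0])
        true_plane = (sp.focal_z_um - sp.reference_z_um) / 0.250  # = 4
        assert abs(pre.best_focus_plane - true_plane) <= 1

    def test_empty_stack_rejected(self):
        with pytest.raises(ValueError):
            preanalyze_stack(np.zeros((0, 4, 4)))
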