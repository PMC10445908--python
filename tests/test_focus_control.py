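"""Autofocus calibration validity, PID behavior and closed-loop focus lock."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from himscope.focus_control import (
    PRECISION_BOUND_NM,
    CalibrationError,
    PIDController,
    PIDParams,
    calibrate_autofocus,
    find_focus_and_reference,
    fit_calibration,
    run_focus_lock,
)
from himscope.hardware_model import (
    SimClock,
    SimulatedLaserBank,
    SimulatedPiezo,
    SimulatedQPD,
    generate_sample,
    substream,
)


def make_focus_rig(seed=0, noise_v=0.0, drift_rate_nm_s=0.0, gain=0.5):
    clock = SimClock()
    sample = generate_sample(0, seed=seed, drift_rate_nm_s=drift_rate_nm_s,
                             surface_z_um=50.0)
    clock.subscribe(sample.advance)
    piezo = SimulatedPiezo("pz", clock, substream(seed, "pz"))
    lasers = SimulatedLaserBank("ls", clock, substream(seed, "ls"))
    qpd = SimulatedQPD("qpd", clock, substream(seed, "qpd"),
                       gain_v_per_um=gain, noise_v=noise_v)
    lasers.set_ir(True)
    return clock, sample, piezo, lasers, qpd


class TestCalibration:
    def test_noiseless_ramp_is_exact(self):
        clock, sample, piezo, lasers, qpd = make_focus_rig(noise_v=0.0)
        result = calibrate_autofocus(qpd, piezo, lasers, sample, clock)
        assert result.monotonic and result.valid
        assert result.precision_nm <= 1e-6
        assert result.slope_v_per_um == pytest.approx(0.5, abs=1e-9)

    def test_commanded_ramp_excursion_is_two_micron(self):
        clock, sample, piezo, lasers, qpd = make_focus_rig()
        result = calibrate_autofocus(qpd, piezo, lasers, sample, clock)
        zs = [z for z, _ in result.ramp]
        assert len(zs) == 21
        assert max(zs) - min(zs) == pytest.approx(2.0, abs=1e-12)

    def test_mean_precision_tracks_sensor_noise_level(self):
        # QPD noise equivalent to 10 nm RMS (0.005 V at 0.5 V/µm)
        precisions = []
        for seed in range(50):
            clock, sample, piezo, lasers, qpd = make_focus_rig(seed=seed, noise_v=0.005)
            result = calibrate_autofocus(qpd, piezo, lasers, sample, clock)
            precisions.append(result.precision_nm)
            # independent least-squares oracle on the recorded ramp
            zs, sig = np.array(result.ramp).T
            coef, res = np.polyfit(zs, sig, 1), None
            rms = np.sqrt(np.mean((sig - np.polyval(coef, zs)) ** 2))
            assert result.precision_nm == pytest.approx(rms / abs(coef[0]) * 1e3, rel=1e-9)
        assert np.mean(precisions) == pytest.approx(10.0, abs=2.0)

    def test_sign_reversal_invalidates_calibration(self):
        zs = np.linspace(49, 51, 21)
        sig = 0.5 * (zs - 50.0)
        sig[10] = sig[12]  # injected reversal mid-ramp
        result = fit_calibration(zs, sig)
        assert not result.monotonic and not result.valid

    def test_ir_off_and_too_few_steps_refused(self):
        clock, sample, piezo, lasers, qpd = make_focus_rig()
        lasers.set_ir(False)
        with pytest.raises(CalibrationError, match="785"):
            calibrate_autofocus(qpd, piezo, lasers, sample, clock)
        lasers.set_ir(True)
        with pytest.raises(CalibrationError):
            calibrate_autofocus(qpd, piezo, lasers, sample, clock, n_steps=2)

    def test_precision_invariant_under_ramp_reversal(self):
        rng = np.random.default_rng(11)
        zs = np.linspace(49, 51, 21)
        sig = 0.5 * zs + rng.normal(0, 0.01, zs.size)
        fwd = fit_calibration(zs, sig)
        rev = fit_calibration(zs[::-1], sig[::-1])
        assert fwd.precision_nm == pytest.approx(rev.precision_nm, rel=1e-9)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(noise_nm=st.floats(0.0, 60.0), seed=st.integers(0, 2**16))
    def test_validity_rule_matches_fit_oracle(self, noise_nm, seed):
        """valid <=> monotonic AND precision < 30 nm, at any noise level."""
        rng = np.random.default_rng(seed)
        zs = np.linspace(49, 51, 21)
        sig = 0.5 * (zs - 50) + rng.normal(0, noise_nm * 1e-3 * 0.5, zs.size)
        result = fit_calibration(zs, sig)
        slope, icept = np.polyfit(zs, sig, 1)
        rms_nm = np.sqrt(np.mean((sig - (slope * zs + icept)) ** 2)) / abs(slope) * 1e3
        diffs = np.diff(sig)
        mono = bool(np.all(diffs > 0) or np.all(diffs < 0))
        assert result.valid == (mono and rms_nm < PRECISION_BOUND_NM)


class OraclePID:
    """Independent hand-rule PID used to cross-check controller traces."""

    def __init__(self, kp, ki, kd, lo, hi, int_limit):
        self.kp, self.ki, self.kd = kp, ki, kd
        self.lo, self.hi, self.int_limit = lo, hi, int_limit
        self.integral = 0.0
        self.prev = None

    def step(self, e, dt):
        tentative = min(max(self.integral + self.ki * e * dt, -self.int_limit), self.int_limit)
        d = 0.0 if self.prev is None else (e - self.prev) / dt
        u = self.kp * e + tentative + self.kd * d
        if u > self.hi:
            u = self.hi
        elif u < self.lo:
            u = self.lo
        else:
            self.integral = tentative
        self.prev = e
        return u


class TestPID:
    def test_zero_error_zero_output(self):
        pid = PIDController(PIDParams())
        assert pid.step(0.0) == 0.0

    def test_pure_proportional(self):
        pid = PIDController(PIDParams(kp=0.7, ki=0.0, kd=0.0))
        assert pid.step(2.0) == pytest.approx(1.4)

    def test_saturating_step_matches_hand_simulated_trace(self):
        params = PIDParams(kp=0.5, ki=1.0, kd=0.0, output_limits=(-1.0, 1.0),
                           integral_limit=10.0, period_s=1.0)
        pid = PIDController(params)
        errors = [1.0, 1.0, -0.2, -0.2, 0.0]
        # hand-computed: clamp at +1 with frozen integral for the first two
        expected = [1.0, 1.0, -0.3, -0.5, -0.4]
        got = [pid.step(e, 1.0) for e in errors]
        assert got == pytest.approx(expected)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.floats(-3, 3), min_size=1, max_size=20))
    def test_controller_equals_independent_rule_oracle(self, errors):
        params = PIDParams(kp=0.6, ki=0.4, kd=0.1, output_limits=(-2.0, 2.0),
                           integral_limit=3.0, period_s=0.5)
        pid = PIDController(params)
        oracle = OraclePID(0.6, 0.4, 0.1, -2.0, 2.0, 3.0)
        for e in errors:
            assert pid.step(e, 0.5) == pytest.approx(oracle.step(e, 0.5))


def oracle_lock_trace(rate_nm_s, n_iter, params, z0=50.0, s0=50.0, step_at=None,
                      step_nm=0.0):
    """Reference discrete closed loop: read, correct, drift one period."""
    oracle = OraclePID(params.kp, params.ki, params.kd,
                       params.output_limits[0], params.output_limits[1],
                       params.integral_limit)
    z, s, trace = z0, s0, []
    for k in range(n_iter):
        if step_at is not None and k == step_at:
            s += step_nm * 1e-3
        e_um = s - z
        trace.append(e_um * 1e3)
        z += oracle.step(e_um, params.period_s)
        s += rate_nm_s * params.period_s * 1e-3
    return trace


class TestFocusLock:
    def test_equilibrium_holds_exactly_without_drift_or_noise(self):
        clock, sample, piezo, lasers, qpd = make_focus_rig(noise_v=0.0)
        cal = calibrate_autofocus(qpd, piezo, lasers, sample, clock)
        setpoint = qpd.read(sample, piezo.position_um, lasers.state).signal_v
        trace = run_focus_lock(setpoint, cal, PIDParams(), 2.0,
                               qpd, piezo, lasers, sample, clock)
        assert max(abs(e) for _, e in trace) == 0.0

    def test_linear_drift_error_stays_within_oracle_bound(self):
        params = PIDParams()
        clock, sample, piezo, lasers, qpd = make_focus_rig(noise_v=0.0,
                                                           drift_rate_nm_s=10.0)
        cal = calibrate_autofocus(qpd, piezo, lasers, sample, clock)
        setpoint = qpd.read(sample, piezo.position_um, lasers.state).signal_v
        trace = run_focus_lock(setpoint, cal, params, 20.0,
                               qpd, piezo, lasers, sample, clock)
        errors = [e for _, e in trace]
        oracle = oracle_lock_trace(10.0, len(errors), params)
        ss_impl = max(abs(e) for e in errors[-30:])
        ss_oracle = max(abs(e) for e in oracle[-30:])
        assert ss_impl <= ss_oracle * 1.05 + 0.5  # nm

    def test_step_disturbance_recovers_into_band_like_oracle(self):
        params = PIDParams()
        clock, sample, piezo, lasers, qpd = make_focus_rig(noise_v=0.0)
        cal = calibrate_autofocus(qpd, piezo, lasers, sample, clock)
        setpoint = qpd.read(sample, piezo.position_um, lasers.state).signal_v
        run_focus_lock(setpoint, cal, params, 1.0, qpd, piezo, lasers, sample, clock)
        sample.surface_z_um += 0.5  # 500 nm step disturbance
        trace = run_focus_lock(setpoint, cal, params, 15.0,
                               qpd, piezo, lasers, sample, clock)
        errors = [abs(e) for _, e in trace]
        oracle = [abs(e) for e in oracle_lock_trace(0.0, len(errors), params,
                                                    step_at=0, step_nm=500.0)]

        def recovery(seq, band=30.0):
            for k in range(len(seq)):
                if all(v <= band for v in seq[k:]):
                    return k
            return len(seq)

        assert recovery(errors) <= recovery(oracle) + 3
        assert max(errors[recovery(errors):]) <= 30.0

    def test_lock_refused_on_invalid_calibration(self):
        clock, sample, piezo, lasers, qpd = make_focus_rig()
        zs = np.linspace(49, 51, 21)
        sig = 0.5 * (zs - 50)
        sig[5] = sig[7]
        bad = fit_calibration(zs, sig)
        with pytest.raises(CalibrationError):
            run_focus_lock(0.0, bad, PIDParams(), 1.0, qpd, piezo, lasers, sample, clock)

    def test_aggressive_gains_never_leave_piezo_travel(self):
        params = PIDParams(kp=50.0, ki=10.0, output_limits=(-80.0, 80.0),
                           integral_limit=80.0)
        clock, sample, piezo, lasers, qpd = make_focus_rig(noise_v=0.01,
                                                           drift_rate_nm_s=100.0)
        cal = calibrate_autofocus(qpd, piezo, lasers, sample, clock)
        setpoint = qpd.read(sample, piezo.position_um, lasers.state).signal_v
        run_focus_lock(setpoint, cal, params, 10.0, qpd, piezo, lasers, sample, clock)
        lo, hi = piezo.travel_um
        assert lo <= piezo.position_um <= hi


class TestFocusSearch:
    def test_reference_position_arithmetic(self):
        clock, sample, piezo, lasers, qpd = make_focus_rig(noise_v=0.0)
        cal = calibrate_autofocus(qpd, piezo, lasers, sample, clock)
        setpoint = qpd.read(sample, piezo.position_um, lasers.state).signal_v
        sp = find_focus_and_reference(setpoint, cal, qpd, piezo, lasers, sample, clock,
                                      below_offset_um=1.5)
        assert sp.focal_z_um == pytest.approx(50.0, abs=1e-3)
        assert sp.reference_z_um == pytest.approx(sp.focal_z_um - 1.5, abs=1e-12)

    def test_idempotent_when_already_at_setpoint(self):
        clock, sample, piezo, lasers, qpd = make_focus_rig(noise_v=0.0)
        cal = calibrate_autofocus(qpd, piezo, lasers, sample, clock)
        setpoint = qpd.read(sample, piezo.position_um, lasers.state).signal_v
        z_before = piezo.position_um
        sp = find_focus_and_reference(setpoint, cal, qpd, piezo, lasers, sample, clock)
        assert sp.focal_z_um == pytest.approx(z_before, abs=2e-3)

    def test_recovers_known_surface_shift_within_30nm(self):
        clock, sample, piezo, lasers, qpd = make_focus_rig(noise_v=0.005)
        cal = calibrate_autofocus(qpd, piezo, lasers, sample, clock)
        setpoint = qpd.read(sample, piezo.position_um, lasers.state).signal_v
        z_focal_0 = find_focus_and_reference(setpoint, cal, qpd, piezo, lasers,
                                             sample, clock).focal_z_um
        sample.surface_z_um += 0.3  # 300 nm simulated shift
        z_focal_1 = find_focus_and_reference(setpoint, cal, qpd, piezo, lasers,
                                             sample, clock).focal_z_um
        assert (z_focal_1 - z_focal_0) * 1e3 == pytest.approx(300.0, abs=30.0)
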